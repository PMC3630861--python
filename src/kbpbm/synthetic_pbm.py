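"""Synthetic two-channel PBM intensities driven by energy PWM occupancy.

The simulator is a Boltzmann two-state occupancy model: each sliding window on
either strand of a probe is bound with probability ``logistic(score - mu)``,
where ``score`` is the sum of per-position log-odds of the window against the
protein's energy matrix and ``mu`` is a chemical potential.  Probe occupancy
(the expected number of bound windows) sets the specific Cy5 signal; the Cy3
channel reads the double-stranding efficiency of the spot.  Both channels
share a per-spot-family double-stranding factor and carry independent
multiplicative log-normal measurement noise, so the Cy3 normalization of Cy5
used downstream is exactly the right correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InputError
from .probe_design import ProbeDesign

BASES = "ACGT"
_BASE_INDEX = {ord(b): i for i, b in enumerate(BASES)}
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMPLEMENT[_a] = _b


@dataclass(frozen=True)
class EnergyPWM:
    """Log-odds scoring matrix (rows A,C,G,T) plus a chemical potential."""

    name: str
    matrix: np.ndarray
    mu: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise InputError(f"PWM matrix must be 4 x width, got shape {m.shape}")
        if not np.isfinite(m).all() or not np.isfinite(self.mu):
            raise InputError("PWM matrix and mu must be finite")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    def score(self, kmer: str) -> float:
        """Log-odds score of a single window (must equal the PWM width)."""
        if len(kmer) != self.width:
            raise InputError(f"window length {len(kmer)} != PWM width {self.width}")
        idx = _encode_seq(kmer)
        return float(self.matrix[idx, np.arange(self.width)].sum())


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise and gain structure of the two-channel readout.

    sigma_meas : SD of log-normal measurement noise, independent per row.
    sigma_ds   : SD of the log-normal per-spot-family double-stranding factor,
                 shared between channels and replicates.
    beta0      : Cy5 background (arbitrary fluorescence units).
    beta1      : Cy5 gain per unit occupancy.
    gamma      : Cy3 gain.
    """

    sigma_meas: float = 0.05
    sigma_ds: float = 0.3
    beta0: float = 100.0
    beta1: float = 5000.0
    gamma: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_meas", "sigma_ds"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        for name in ("beta0", "beta1", "gamma"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")


def _encode_seq(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(raw, np.frombuffer(b"ACGT", dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise InputError(f"non-ACGT character {seq[pos]!r} at position {pos + 1}")
    idx = np.zeros(raw.shape, dtype=np.int64)
    for code, i in _BASE_INDEX.items():
        idx[raw == code] = i
    return idx


def _window_scores(idx: np.ndarray, pwm: EnergyPWM) -> np.ndarray:
    """Scores of all windows of one encoded strand (1-D index array)."""
    w = pwm.width
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return pwm.matrix[windows, np.arange(w)].sum(axis=1)


def probe_occupancy(sequence: str, pwm: EnergyPWM) -> float:
    """Expected number of bound windows over both strands of a probe.

    Sum over all windows on the top and bottom strands of
    ``logistic(score(window) - mu)``; bounded by ``2 * (L - width + 1)``.
    """
    if len(sequence) < pwm.width:
        raise InputError(
            f"sequence length {len(sequence)} is shorter than PWM width {pwm.width}"
        )
    fwd = _encode_seq(sequence)
    raw = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    rev = _encode_seq(_COMPLEMENT[raw][::-1].tobytes().decode("ascii"))
    occ = expit(_window_scores(fwd, pwm) - pwm.mu).sum()
    occ += expit(_window_scores(rev, pwm) - pwm.mu).sum()
    return float(occ)


# ---------------------------------------------------------------------------
# the default four-dimer suite
# ---------------------------------------------------------------------------

def _pwm_from_bonuses(
    name: str,
    bonuses: list[dict[str, float]],
    mu_frac: float,
    penalty_frac: float = 0.6,
) -> EnergyPWM:
    """Build a log-odds matrix from per-position favored-base bonuses.

    Bases not listed at a constrained position are penalized by
    ``penalty_frac`` times the position's top bonus, as in a genuine
    log-odds matrix; this keeps off-frame windows from accumulating partial
    matches.  Unconstrained positions score 0 for every base.
    """
    m = np.zeros((4, len(bonuses)))
    for j, pos in enumerate(bonuses):
        if not pos:
            continue
        top = max(pos.values())
        m[:, j] = -penalty_frac * top
        for base, w in pos.items():
            m[BASES.index(base), j] = w
    mu = mu_frac * float(m.max(axis=0).sum())
    return EnergyPWM(name=name, matrix=m, mu=mu)


# Width-10 energy matrices aligned to positions 1-10 of the 11-mer kappaB
# consensus RGGRNNHHYYB (frame RGGRNNHHYY), so the canonical TNF kappaB site
# GGGAATTTCC is the top-scoring k-mer of the anemone-like matrix.  The suite
# encodes the cross-protein structure the analysis is meant to recover:
# divergence from nv_p50_like ordered p52-like < p50-like < RelA-like, with
# the human-p50-like matrix biased toward a 3' C-run whose last position
# tolerates C/T (asymmetric half-site preference).
_SUITE_DEF: list[tuple[str, list[dict[str, float]], float]] = [
    (
        "nv_p50_like",
        [
            {"G": 1.2, "A": 0.5}, {"G": 2.4}, {"G": 2.4}, {"A": 1.1, "G": 0.7},
            {"A": 0.4}, {"A": 0.2, "T": 0.2}, {"T": 1.1, "A": 0.3},
            {"T": 1.1, "C": 0.5}, {"C": 2.4, "T": 0.3}, {"C": 2.4, "T": 0.3},
        ],
        0.55,
    ),
    (
        "hs_p52_like",
        [
            {"G": 1.1, "A": 0.6}, {"G": 2.4}, {"G": 2.4}, {"A": 1.0, "G": 0.8},
            {"A": 0.3, "C": 0.2}, {"T": 0.3}, {"T": 1.0, "C": 0.5},
            {"T": 1.0, "C": 0.6}, {"C": 2.5}, {"C": 2.5},
        ],
        0.55,
    ),
    (
        "hs_p50_like",
        [
            {"G": 0.6, "A": 0.6}, {"G": 2.4}, {"G": 2.4}, {"A": 0.6, "C": 0.4},
            {"C": 0.8}, {"C": 1.4}, {"C": 2.0, "T": 0.3},
            {"C": 2.2}, {"C": 2.4}, {"C": 1.0, "T": 1.5},
        ],
        0.55,
    ),
    (
        "relA_like",
        [
            {"A": 1.2}, {"G": 2.2}, {"G": 2.2}, {"A": 2.4},
            {"A": 1.6}, {"T": 1.6}, {"C": 1.6, "T": 0.4},
            {"C": 1.8, "T": 0.4}, {"T": 2.0, "C": 0.4}, {"T": 1.8, "C": 0.4},
        ],
        0.55,
    ),
]


def default_dimer_suite() -> dict[str, EnergyPWM]:
    """Four NF-kB-like dimers: nv_p50_like, hs_p52_like, hs_p50_like, relA_like."""
    return {name: _pwm_from_bonuses(name, table, mu) for name, table, mu in _SUITE_DEF}


# ---------------------------------------------------------------------------
# intensity simulation
# ---------------------------------------------------------------------------

def batch_occupancies(sequences: list[str], pwm: EnergyPWM) -> np.ndarray:
    """Vectorized :func:`probe_occupancy` over equal-length sequences."""
    if not sequences:
        return np.zeros(0)
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        return np.array([probe_occupancy(s, pwm) for s in sequences])
    if L < pwm.width:
        raise InputError(f"sequence length {L} is shorter than PWM width {pwm.width}")
    raw = np.frombuffer("".join(s.upper() for s in sequences).encode("ascii"),
                        dtype=np.uint8).reshape(len(sequences), L)
    rev = _COMPLEMENT[raw][:, ::-1]
    w = pwm.width
    occ = np.zeros(len(sequences))
    for strand in (raw, rev):
        idx = np.zeros(strand.shape, dtype=np.int64)
        for code, i in _BASE_INDEX.items():
            idx[strand == code] = i
        windows = np.lib.stride_tricks.sliding_window_view(idx, w, axis=1)
        scores = pwm.matrix[windows, np.arange(w)].sum(axis=2)
        occ += expit(scores - pwm.mu).sum(axis=1)
    return occ


def simulate_intensities(
    design: ProbeDesign,
    pwms: dict[str, EnergyPWM] | list[EnergyPWM],
    noise: NoiseModel,
) -> pd.DataFrame:
    """Simulate a long-format two-channel intensity table.

    For spot family *i* (one core x flank combination) a double-stranding
    factor ``delta_i ~ LogNormal(0, sigma_ds^2)`` is drawn once per protein
    and shared between channels and replicates.  Per feature row,
    ``Cy3 = gamma * delta_i * eps`` and
    ``Cy5 = delta_i * (beta0 + beta1 * occupancy_i) * eps'`` with independent
    ``eps, eps' ~ LogNormal(0, sigma_meas^2)``.  Fully reproducible for a
    fixed :attr:`NoiseModel.seed`.
    """
    if isinstance(pwms, dict):
        pwm_list = list(pwms.values())
    else:
        pwm_list = list(pwms)
    if not design.features:
        raise InputError("design has no features")

    families: list[tuple[str, str]] = []
    fam_index: dict[tuple[str, str], int] = {}
    feat_fam = np.empty(design.n_features, dtype=np.int64)
    for i, f in enumerate(design.features):
        key = (f.core_id, f.flank_id)
        if key not in fam_index:
            fam_index[key] = len(families)
            families.append(key)
        feat_fam[i] = fam_index[key]
    seq_of = {(f.core_id, f.flank_id): f.full_sequence for f in design.features}
    fam_seqs = [seq_of[key] for key in families]

    ss = np.random.SeedSequence(noise.seed)
    children = ss.spawn(1 + 2 * len(pwm_list))
    ds_rng = np.random.Generator(np.random.PCG64(children[0]))
    z_ds = ds_rng.standard_normal((len(pwm_list), len(families)))

    n = design.n_features
    feat_ids = [f.feature_id for f in design.features]
    reps = [f.replicate for f in design.features]
    frames = []
    for p, pwm in enumerate(pwm_list):
        occ = batch_occupancies(fam_seqs, pwm)
        delta = np.exp(noise.sigma_ds * z_ds[p])
        rng3 = np.random.Generator(np.random.PCG64(children[1 + 2 * p]))
        rng5 = np.random.Generator(np.random.PCG64(children[2 + 2 * p]))
        eps3 = np.exp(noise.sigma_meas * rng3.standard_normal(n))
        eps5 = np.exp(noise.sigma_meas * rng5.standard_normal(n))
        cy3 = noise.gamma * delta[feat_fam] * eps3
        cy5 = delta[feat_fam] * (noise.beta0 + noise.beta1 * occ[feat_fam]) * eps5
        for channel, vals in (("Cy3", cy3), ("Cy5", cy5)):
            frames.append(
                pd.DataFrame(
                    {
                        "feature_id": feat_ids,
                        "protein": pwm.name,
                        "channel": channel,
                        "replicate": reps,
                        "intensity": vals,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_intensities(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n",
                 float_format="%.10g")


def read_intensities(path) -> pd.DataFrame:
    """Read a long-format intensity TSV; extra columns are tolerated."""
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "protein", "channel", "replicate", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"intensity table missing column(s) {sorted(missing)}")
    return df
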