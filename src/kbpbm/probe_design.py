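"""Degenerate-consensus probe design for double-stranded DNA microarrays.

A degenerate IUPAC consensus (the default is the generalized kappaB site
``RGGRNNHHYYB``) is expanded into its full k-mer space, the space is embedded
by classical principal coordinate analysis (PCoA) of pairwise Hamming
distances, and a representative core subset is selected by k-medoids.  Cores
are then crossed with flanking sequences and technical replicates into the
physical feature list of an array, subject to a feature-capacity budget.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DesignError, InputError, ParseError

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes mapped to their (sorted) base sets.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Generalized kappaB-site consensus used as the package-wide default.
DEFAULT_CONSENSUS = "RGGRNNHHYYB"

#: Number of features available on one 15K array sector.
DEFAULT_CAPACITY = 15_000


@dataclass(frozen=True)
class Flank:
    """Constant sequence pair surrounding every probe core."""

    flank_id: str
    left: str
    right: str

    def __post_init__(self) -> None:
        for part in (self.left, self.right):
            bad = set(part) - set("ACGT")
            if bad:
                raise InputError(
                    f"flank {self.flank_id!r} contains non-ACGT characters: {sorted(bad)}"
                )


#: Default flank set.  Flank ``fA`` reproduces the constant arms of the
#: biotinylated kappaB pulldown oligonucleotide (AGCTGGGCAT ... AACTCT); the
#: other three are fixed GC-balanced arms of the same lengths.
DEFAULT_FLANKS: tuple[Flank, ...] = (
    Flank("fA", "AGCTGGGCAT", "AACTCT"),
    Flank("fB", "TGACTCGATG", "CATGTC"),
    Flank("fC", "GATCCATTGC", "TGACAG"),
    Flank("fD", "CTAGGTACAG", "ACTGTC"),
)


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC degenerate consensus string."""

    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise InputError("consensus must be non-empty")
        norm = self.consensus.upper()
        for pos, char in enumerate(norm, start=1):
            if char not in IUPAC_CODES:
                raise InputError(
                    f"invalid IUPAC character {char!r} at position {pos} of consensus"
                )
        object.__setattr__(self, "consensus", norm)

    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def space_size(self) -> int:
        """Product of the per-position degeneracies."""
        return math.prod(len(IUPAC_CODES[c]) for c in self.consensus)

    def matches(self, kmer: str) -> bool:
        return len(kmer) == self.length and all(
            b in IUPAC_CODES[c] for b, c in zip(kmer.upper(), self.consensus)
        )


@dataclass(frozen=True)
class KmerSpace:
    """The ordered set of all k-mers matching a degenerate consensus."""

    motif: DegenerateMotif
    kmers: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.kmers)

    @property
    def width(self) -> int:
        return self.motif.length


@dataclass(frozen=True)
class PCoAEmbedding:
    """Classical (Gower) principal-coordinate embedding of a distance matrix.

    ``coordinates`` has one column per retained positive-eigenvalue axis;
    column *j* has squared norm ``eigenvalues[j]``.  ``negative_mass_fraction``
    records the magnitude of the dropped negative spectrum relative to the
    positive mass (non-zero whenever the input metric is not Euclidean).
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    retained_fraction: float
    negative_mass_fraction: float = 0.0

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class Feature:
    """One physical spot on the array."""

    feature_id: str
    core_id: str
    flank_id: str
    replicate: int
    full_sequence: str


@dataclass(frozen=True)
class ProbeDesign:
    """Cores x flanks x replicates, with array-capacity bookkeeping."""

    cores: tuple[str, ...]
    core_ids: tuple[str, ...]
    flanks: tuple[Flank, ...]
    replicates: int
    capacity: int
    features: tuple[Feature, ...] = field(repr=False)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def core_sequence(self, core_id: str) -> str:
        return dict(zip(self.core_ids, self.cores))[core_id]

    def to_frame(self) -> pd.DataFrame:
        seq_of = dict(zip(self.core_ids, self.cores))
        return pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self.features],
                "core_id": [f.core_id for f in self.features],
                "core_seq": [seq_of[f.core_id] for f in self.features],
                "flank_id": [f.flank_id for f in self.features],
                "replicate": [f.replicate for f in self.features],
                "full_seq": [f.full_sequence for f in self.features],
            }
        )


# ---------------------------------------------------------------------------
# k-mer space expansion
# ---------------------------------------------------------------------------

def expand_iupac(motif: DegenerateMotif | str) -> KmerSpace:
    """Expand a degenerate consensus into its full k-mer space.

    Returns every DNA string matching the consensus exactly once, in
    lexicographic order (each IUPAC code's base set is stored sorted, so the
    cartesian product is emitted already sorted).
    """
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    groups = [IUPAC_CODES[c] for c in motif.consensus]
    kmers = tuple("".join(p) for p in itertools.product(*groups))
    return KmerSpace(motif=motif, kmers=kmers)


def _encode(kmers: Sequence[str]) -> np.ndarray:
    width = len(kmers[0])
    flat = "".join(kmers)
    return np.frombuffer(flat.encode("ascii"), dtype=np.uint8).reshape(len(kmers), width)


def hamming_matrix(space: KmerSpace | Sequence[str]) -> np.ndarray:
    """Symmetric matrix of pairwise Hamming distances between equal-length k-mers."""
    kmers = space.kmers if isinstance(space, KmerSpace) else tuple(space)
    if not kmers:
        return np.zeros((0, 0), dtype=np.int16)
    widths = {len(k) for k in kmers}
    if len(widths) != 1:
        raise InputError(f"k-mers have unequal lengths: {sorted(widths)}")
    arr = _encode(kmers)
    n = len(kmers)
    out = np.empty((n, n), dtype=np.int16)
    # chunked broadcast keeps peak memory at O(chunk * n * width)
    chunk = max(1, 2**22 // max(1, n * arr.shape[1]))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        out[start:stop] = (arr[start:stop, None, :] != arr[None, :, :]).sum(
            axis=-1, dtype=np.int16
        )
    return out


# ---------------------------------------------------------------------------
# principal coordinate analysis
# ---------------------------------------------------------------------------

def pcoa(D: np.ndarray, retained_fraction: float = 0.9) -> PCoAEmbedding:
    """Classical (Gower) principal coordinate decomposition of a distance matrix.

    Double-centers ``-1/2 * D**2``, eigendecomposes, and keeps the leading
    positive-eigenvalue axes up to ``retained_fraction`` of the positive
    eigenvalue mass.  Coordinates are eigenvectors scaled by the square root
    of their eigenvalue; negative eigenvalues (possible for non-Euclidean
    metrics such as Hamming) are dropped and their mass fraction logged.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError(f"distance matrix must be square, got shape {D.shape}")
    if not (0.0 < retained_fraction <= 1.0):
        raise InputError("retained_fraction must be in (0, 1]")
    if (D < 0).any():
        raise InputError("distance matrix has negative entries")
    if not np.allclose(D, D.T, atol=1e-8):
        raise InputError("distance matrix is not symmetric")
    if not np.allclose(np.diagonal(D), 0.0, atol=1e-12):
        raise InputError("distance matrix diagonal is not zero")

    n = D.shape[0]
    if n == 0:
        return PCoAEmbedding(np.zeros((0, 0)), np.zeros(0), retained_fraction)

    A = -0.5 * D * D
    row_mean = A.mean(axis=1, keepdims=True)
    col_mean = A.mean(axis=0, keepdims=True)
    B = A - row_mean - col_mean + A.mean()
    del A

    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0) * n * np.finfo(float).eps
    pos = eigvals > tol
    neg_mass = float(-eigvals[eigvals < -tol].sum())
    pos_vals = eigvals[pos]
    pos_vecs = eigvecs[:, pos]
    pos_mass = float(pos_vals.sum())
    neg_frac = neg_mass / pos_mass if pos_mass > 0 else 0.0
    if neg_frac > 0:
        logger.warning(
            "PCoA dropped negative eigenvalues carrying %.3f of the positive mass",
            neg_frac,
        )

    if pos_mass == 0.0:
        return PCoAEmbedding(np.zeros((n, 0)), np.zeros(0), retained_fraction, neg_frac)

    cum = np.cumsum(pos_vals) / pos_mass
    m = int(np.searchsorted(cum, retained_fraction - 1e-12) + 1)
    vals = pos_vals[:m]
    vecs = pos_vecs[:, :m].copy()
    # deterministic sign: largest-magnitude loading of each axis is positive
    flip = vecs[np.abs(vecs).argmax(axis=0), np.arange(m)] < 0
    vecs[:, flip] *= -1.0
    coords = vecs * np.sqrt(vals)
    return PCoAEmbedding(coords, vals, retained_fraction, neg_frac)


# ---------------------------------------------------------------------------
# representative selection (k-medoids, PAM build + swap)
# ---------------------------------------------------------------------------

def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    first = int(D.sum(axis=1).argmin())  # argmin breaks ties at smallest index
    medoids = [first]
    d1 = D[first].copy()
    for _ in range(1, k):
        gains = np.maximum(d1[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(gains.argmax())
        medoids.append(best)
        np.minimum(d1, D[best], out=d1)
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], max_sweeps: int = 200) -> list[int]:
    n = D.shape[0]
    medoids = sorted(medoids)
    for _ in range(max_sweeps):
        med = np.asarray(medoids)
        Dm = D[med]  # (k, n)
        nearest = Dm.argmin(axis=0)
        d1 = Dm[nearest, np.arange(n)]
        if len(medoids) > 1:
            Dm2 = Dm.copy()
            Dm2[nearest, np.arange(n)] = np.inf
            d2 = Dm2.min(axis=0)
        else:
            d2 = np.full(n, np.inf)
        best_delta, best_swap = -1e-12, None
        in_medoids = np.zeros(n, dtype=bool)
        in_medoids[medoids] = True
        for h in range(n):
            if in_medoids[h]:
                continue
            base = np.minimum(0.0, D[h] - d1)
            rem = np.minimum(D[h], d2) - d1
            adj = rem - base
            deltas = base.sum() + np.bincount(nearest, weights=adj, minlength=len(medoids))
            i = int(deltas.argmin())
            if deltas[i] < best_delta:
                best_delta, best_swap = float(deltas[i]), (i, h)
        if best_swap is None:
            break
        i, h = best_swap
        medoids[i] = h
        medoids.sort()
    return medoids


def kmedoids_objective(D: np.ndarray, medoids: Sequence[int]) -> float:
    """Sum of point-to-nearest-medoid distances."""
    return float(D[np.asarray(medoids)].min(axis=0).sum())


def select_representatives(
    embedding: PCoAEmbedding, k: int, seed: int = 0
) -> np.ndarray:
    """Select ``k`` representative points by k-medoids (PAM build + swap).

    Operates on Euclidean distances in the retained coordinate space.  The
    PAM heuristic used here is fully deterministic (ties break at the lowest
    point index, i.e. lexicographically when points are sorted k-mers); the
    ``seed`` argument is accepted for interface stability and reproducibility
    contracts.
    """
    n = embedding.n_points
    if not (1 <= k <= n):
        raise InputError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return np.arange(n)
    if embedding.n_axes == 0:
        # degenerate: all points coincide; any subset is optimal
        return np.arange(k)
    D = squareform(pdist(embedding.coordinates))
    medoids = _pam_build(D, k)
    medoids = _pam_swap(D, medoids)
    return np.asarray(sorted(medoids))


# ---------------------------------------------------------------------------
# array assembly and design I/O
# ---------------------------------------------------------------------------

def _coerce_flanks(flanks: Iterable[Flank | tuple]) -> tuple[Flank, ...]:
    out = []
    for i, f in enumerate(flanks):
        if isinstance(f, Flank):
            out.append(f)
        elif len(f) == 3:
            out.append(Flank(*f))
        elif len(f) == 2:
            out.append(Flank(f"f{i}", *f))
        else:
            raise InputError(f"cannot interpret flank specification {f!r}")
    return tuple(out)


def assemble_probes(
    cores: Sequence[str],
    flanks: Iterable[Flank | tuple] = DEFAULT_FLANKS,
    replicates: int = 3,
    capacity: int = DEFAULT_CAPACITY,
) -> ProbeDesign:
    """Cross cores with flanks and replicates into the physical feature list.

    Raises :class:`DesignError` when the factorial exceeds ``capacity``.
    Feature identifiers are deterministic (``<core_id>_<flank_id>_r<rep>``)
    and ``full_sequence = left + core + right``.
    """
    flanks = _coerce_flanks(flanks)
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    if capacity < 1:
        raise InputError("capacity must be >= 1")
    required = len(cores) * len(flanks) * replicates
    if required > capacity:
        raise DesignError(
            f"design requires {required} features "
            f"({len(cores)} cores x {len(flanks)} flanks x {replicates} replicates) "
            f"but the array holds only {capacity}"
        )
    core_ids = tuple(f"c{i:04d}" for i in range(len(cores)))
    features = []
    for core_id, core in zip(core_ids, cores):
        for flank in flanks:
            for rep in range(1, replicates + 1):
                features.append(
                    Feature(
                        feature_id=f"{core_id}_{flank.flank_id}_r{rep}",
                        core_id=core_id,
                        flank_id=flank.flank_id,
                        replicate=rep,
                        full_sequence=flank.left + core + flank.right,
                    )
                )
    return ProbeDesign(
        cores=tuple(cores),
        core_ids=core_ids,
        flanks=flanks,
        replicates=replicates,
        capacity=capacity,
        features=tuple(features),
    )


DESIGN_COLUMNS = ["feature_id", "core_id", "core_seq", "flank_id", "replicate", "full_seq"]


def write_design(design: ProbeDesign, path) -> None:
    """Write a design as a TSV with a ``# capacity=N`` header comment."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# capacity={design.capacity}\n")
        design.to_frame().to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_design(path) -> ProbeDesign:
    """Read a design TSV written by :func:`write_design` (round-trip identity)."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        capacity = DEFAULT_CAPACITY
        offset = 1
        if first.startswith("#"):
            try:
                capacity = int(first.split("=", 1)[1])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"line 1: malformed capacity comment {first!r}") from exc
            offset = 2
            header_line = fh.readline()
        else:
            header_line = first
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in DESIGN_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"line {offset}: missing required column(s) {missing}")
        try:
            df = pd.read_csv(fh, sep="\t", names=header, dtype=str)
        except pd.errors.EmptyDataError:
            return ProbeDesign((), (), (), 1, capacity, ())
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError as exc:
        raise ParseError(f"non-integer replicate value in {path}") from exc

    core_ids = list(dict.fromkeys(df["core_id"]))
    seq_of = {}
    for row in df.itertuples(index=False):
        prev = seq_of.setdefault(row.core_id, row.core_seq)
        if prev != row.core_seq:
            raise ParseError(f"core {row.core_id} maps to conflicting sequences")
    cores = tuple(seq_of[c] for c in core_ids)

    flank_ids = list(dict.fromkeys(df["flank_id"]))
    flanks = []
    for fid in flank_ids:
        sub = df[df["flank_id"] == fid]
        candidates = None
        for i, row in enumerate(sub.itertuples(index=False)):
            full, core = row.full_seq, row.core_seq
            splits = {
                (full[:p], full[p + len(core):])
                for p in range(len(full) - len(core) + 1)
                if full[p : p + len(core)] == core
            }
            if not splits:
                line = int(sub.index[i]) + offset + 1
                raise ParseError(
                    f"line {line}: full_seq does not contain core_seq for flank {fid}"
                )
            candidates = splits if candidates is None else candidates & splits
            if len(candidates) == 1:
                break
        if not candidates:
            raise ParseError(f"inconsistent flank arms for flank {fid}")
        left, right = min(candidates, key=lambda lr: len(lr[0]))
        flanks.append(Flank(fid, left, right))

    replicates = int(df["replicate"].max())
    expected = len(cores) * len(flanks) * replicates
    if len(df) != expected:
        raise ParseError(
            f"feature table is not a complete factorial: {len(df)} rows, "
            f"expected {expected}"
        )
    features = tuple(
        Feature(r.feature_id, r.core_id, r.flank_id, int(r.replicate), r.full_seq)
        for r in df.itertuples(index=False)
    )
    return ProbeDesign(cores, tuple(core_ids), tuple(flanks), replicates, capacity, features)
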