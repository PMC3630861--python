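"""Cross-protein comparison of binding profiles and top-N DNA barcodes.

Profiles are compared by Pearson correlation of matched z-score vectors and
by agglomerative clustering (Euclidean distance, complete linkage).  A
protein's "barcode" is the position frequency matrix (with per-position
information content) of its top-N highest-z probe cores, together with a
half-site symmetry score contrasting the 5' GG and 3' CC signatures of the
kappaB motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import InputError
from .intensity_processing import BindingProfile
from .probe_design import ProbeDesign

_BASES = "ACGT"


@dataclass(frozen=True)
class CorrelationMatrix:
    proteins: tuple[str, ...]
    values: np.ndarray

    def pair(self, a: str, b: str) -> float:
        i, j = self.proteins.index(a), self.proteins.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.proteins, columns=self.proteins)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history over named leaves.

    ``merges`` lists (node_a, node_b, height) with scipy node numbering
    (leaves 0..n-1 in ``names`` order, internal nodes n, n+1, ...); ``Z`` is
    the full scipy linkage matrix.
    """

    names: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[str, ...]
    Z: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def outgroup(self) -> str | None:
        """Name of the leaf joining alone at the final merge, if any."""
        n = len(self.names)
        a, b, _ = self.merges[-1]
        if a < n:
            return self.names[a]
        if b < n:
            return self.names[b]
        return None

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = len(self.names)
        height = {i: 0.0 for i in range(n)}
        label = {i: self.names[i] for i in range(n)}
        for idx, (a, b, h) in enumerate(self.merges):
            node = n + idx
            parts = []
            for child in (a, b):
                parts.append(f"{label[child]}:{h - height[child]:.10g}")
            label[node] = f"({parts[0]},{parts[1]})"
            height[node] = h
        return label[n + len(self.merges) - 1] + ";"


@dataclass(frozen=True)
class Barcode:
    """Position-frequency summary of a protein's top-N probes."""

    protein: str
    top_kmers: tuple[str, ...]
    pfm: np.ndarray  # 4 x width, columns sum to 1, rows A,C,G,T
    information_content: np.ndarray  # per-position bits in [0, 2]

    @property
    def width(self) -> int:
        return self.pfm.shape[1]


def _aligned_matrix(profiles: Sequence[BindingProfile]) -> tuple[np.ndarray, tuple[str, ...]]:
    if len(profiles) < 2:
        raise InputError("need >= 2 profiles")
    ref = profiles[0].entries.index
    ref_set = set(ref)
    for p in profiles[1:]:
        other = set(p.entries.index)
        if other != ref_set:
            diff = sorted(ref_set ^ other)
            raise InputError(
                f"probe sets differ between {profiles[0].protein!r} and "
                f"{p.protein!r}; symmetric difference: {diff[:10]}"
                + (" ..." if len(diff) > 10 else "")
            )
    X = np.vstack([p.entries.reindex(ref).to_numpy(dtype=float) for p in profiles])
    if (X.std(axis=1, ddof=1) == 0).any():
        raise InputError("a profile has zero variance")
    return X, tuple(p.protein for p in profiles)


def correlation_matrix(profiles: Sequence[BindingProfile]) -> CorrelationMatrix:
    """Pearson correlations between all profile pairs on matched probe order."""
    X, names = _aligned_matrix(profiles)
    return CorrelationMatrix(proteins=names, values=np.corrcoef(X))


def cluster_profiles(
    profiles: Sequence[BindingProfile], metric: str = "euclidean"
) -> Dendrogram:
    """Complete-linkage agglomerative clustering of z-score vectors.

    ``metric`` is ``"euclidean"`` (default) or ``"correlation"`` (1 - r).
    Profiles are ordered by name before clustering so ties resolve
    lexicographically and the result is deterministic.
    """
    if metric not in ("euclidean", "correlation"):
        raise InputError(f"unsupported metric {metric!r}")
    ordered = sorted(profiles, key=lambda p: p.protein)
    X, names = _aligned_matrix(ordered)
    Z = linkage(X, method="complete", metric=metric)
    merges = tuple((int(a), int(b), float(h)) for a, b, h, _ in Z)
    order = tuple(names[i] for i in leaves_list(Z))
    return Dendrogram(names=names, merges=merges, leaf_order=order, Z=Z)


def heatmap_matrix(
    profiles: Sequence[BindingProfile], dendrogram: Dendrogram
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Z-score matrix with columns in leaf order, rows by mean z descending."""
    by_name = {p.protein: p for p in profiles}
    missing = set(dendrogram.names) - set(by_name)
    if missing:
        raise InputError(f"dendrogram names absent from profiles: {sorted(missing)}")
    col_order = list(dendrogram.leaf_order)
    df = pd.DataFrame({name: by_name[name].entries for name in col_order})
    mean_z = df.mean(axis=1)
    row_order = list(
        pd.DataFrame({"mean": -mean_z, "id": df.index.astype(str)})
        .sort_values(["mean", "id"], kind="stable")
        .index
    )
    return df.loc[row_order], row_order, col_order


def top_n_probes(profile: BindingProfile, design: ProbeDesign, n: int = 20) -> list[str]:
    """Core k-mers of the n highest z-scores; ties break lexicographically."""
    if not (1 <= n <= profile.n_probes):
        raise InputError(f"n must be in [1, {profile.n_probes}], got {n}")
    seq_of = dict(zip(design.core_ids, design.cores))
    try:
        ranked = sorted(
            profile.entries.items(), key=lambda kv: (-kv[1], seq_of[kv[0]])
        )
    except KeyError as exc:
        raise InputError(f"profile core {exc.args[0]!r} absent from design") from exc
    return [seq_of[core_id] for core_id, _ in ranked[:n]]


def position_frequency_matrix(
    kmers: Sequence[str], protein: str = ""
) -> Barcode:
    """Exact base frequencies and information content of a k-mer set.

    ``IC_j = 2 + sum_b f_bj * log2(f_bj)`` with ``0 * log 0 = 0``; no
    pseudocounts are applied.
    """
    if not kmers:
        raise InputError("need >= 1 k-mer")
    width = len(kmers[0])
    if any(len(k) != width for k in kmers):
        raise InputError("k-mers have unequal lengths")
    counts = np.zeros((4, width))
    for kmer in kmers:
        for j, base in enumerate(kmer.upper()):
            if base not in _BASES:
                raise InputError(f"non-ACGT character {base!r} in k-mer {kmer!r}")
            counts[_BASES.index(base), j] += 1
    pfm = counts / len(kmers)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(np.where(pfm > 0, pfm, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return Barcode(
        protein=protein,
        top_kmers=tuple(kmers),
        pfm=pfm,
        information_content=ic,
    )


def half_site_symmetry(
    barcode: Barcode,
    left_positions: Sequence[int] | None = None,
    right_positions: Sequence[int] | None = None,
) -> float:
    """Agreement between the 5' G and 3' C half-site signatures, in [0, 1].

    ``s_left`` is the product of G frequencies over ``left_positions`` and
    ``s_right`` the product of C frequencies over ``right_positions``
    (0-based).  The score is ``min/max`` of the two, defined as 1 when both
    vanish.  Defaults for 11-mer barcodes target the consensus GG at
    positions 2-3 and CC at positions 9-10 (1-based).
    """
    if left_positions is None or right_positions is None:
        if barcode.width != 11:
            raise InputError(
                "default half-site positions are defined for 11-mers; "
                f"barcode width is {barcode.width}"
            )
        left_positions = (1, 2)
        right_positions = (8, 9)
    for pos in (*left_positions, *right_positions):
        if not (0 <= pos < barcode.width):
            raise InputError(f"position {pos} out of range for width {barcode.width}")
    g, c = _BASES.index("G"), _BASES.index("C")
    s_left = float(np.prod([barcode.pfm[g, p] for p in left_positions]))
    s_right = float(np.prod([barcode.pfm[c, p] for p in right_positions]))
    if s_left == 0.0 and s_right == 0.0:
        return 1.0
    return min(s_left, s_right) / max(s_left, s_right)


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def write_correlations(cm: CorrelationMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t", lineterminator="\n", float_format="%.6f")


def write_newick(dendrogram: Dendrogram, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(dendrogram.to_newick() + "\n")


def write_meme(barcode: Barcode, path) -> None:
    """Minimal MEME motif format (letter-probability matrix)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {barcode.protein or 'barcode'}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {barcode.width} "
            f"nsites= {len(barcode.top_kmers)}\n"
        )
        for j in range(barcode.width):
            fh.write(" ".join(f"{barcode.pfm[b, j]:.6f}" for b in range(4)) + "\n")


def write_information_content(barcode: Barcode, path) -> None:
    pd.DataFrame(
        {
            "position": np.arange(1, barcode.width + 1),
            "information_bits": barcode.information_content,
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6f")
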