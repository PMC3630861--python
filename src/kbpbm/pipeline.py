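"""End-to-end orchestration: design -> simulate -> process -> compare/barcode.

A :class:`RunConfig` (flat YAML or constructed in code) drives the whole
chain reproducibly from one master seed; :func:`run_all` writes every
intermediate artifact plus a manifest of output hashes.  :func:`make_fixtures`
builds the miniature dataset (32 cores x 2 flanks x 3 replicates) used
throughout the test suite.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import PipelineError
from .intensity_processing import (
    BindingProfile,
    profiles_from_intensities,
    write_zscore_table,
)
from .probe_design import (
    DEFAULT_CAPACITY,
    DEFAULT_CONSENSUS,
    DEFAULT_FLANKS,
    Flank,
    ProbeDesign,
    assemble_probes,
    expand_iupac,
    hamming_matrix,
    pcoa,
    select_representatives,
    write_design,
)
from .profile_analysis import (
    cluster_profiles,
    correlation_matrix,
    half_site_symmetry,
    heatmap_matrix,
    position_frequency_matrix,
    top_n_probes,
    write_correlations,
    write_information_content,
    write_meme,
    write_newick,
)
from .synthetic_pbm import (
    NoiseModel,
    default_dimer_suite,
    simulate_intensities,
    write_intensities,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for one reproducible pipeline run."""

    seed: int
    outdir: str = "kbpbm_run"
    consensus: str = DEFAULT_CONSENSUS
    k: int = 803
    subsample: int | None = None  # embed a seeded subset of the k-mer space
    retained_fraction: float = 0.9
    flanks: list = field(default_factory=lambda: [list(f.__dict__.values()) for f in DEFAULT_FLANKS])
    replicates: int = 3
    capacity: int = DEFAULT_CAPACITY
    suite: str = "default"
    sigma_meas: float = 0.05
    sigma_ds: float = 0.3
    beta0: float = 100.0
    beta1: float = 5000.0
    gamma: float = 500.0
    top_n: int = 20
    pool_flanks: bool = True
    metric: str = "euclidean"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def flank_objects(self) -> tuple[Flank, ...]:
        return tuple(Flank(*f) for f in self.flanks)


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return result

        return wrapped

    return decorator


@_stage("design")
def design_stage(config: RunConfig) -> ProbeDesign:
    space = expand_iupac(config.consensus)
    kmers = list(space.kmers)
    if config.subsample is not None and config.subsample < len(kmers):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(config.seed).spawn(1)[0])
        )
        idx = np.sort(rng.choice(len(kmers), size=config.subsample, replace=False))
        kmers = [kmers[i] for i in idx]
    D = hamming_matrix(kmers)
    embedding = pcoa(D, retained_fraction=config.retained_fraction)
    chosen = select_representatives(embedding, k=config.k, seed=config.seed)
    cores = [kmers[i] for i in chosen]
    logger.info("selected %d representative cores from %d k-mers", len(cores), len(kmers))
    return assemble_probes(
        cores, config.flank_objects(), config.replicates, config.capacity
    )


@_stage("simulate")
def simulate_stage(config: RunConfig, design: ProbeDesign):
    if config.suite != "default":
        raise ValueError(f"unknown PWM suite {config.suite!r}")
    suite = default_dimer_suite()
    noise = NoiseModel(
        sigma_meas=config.sigma_meas,
        sigma_ds=config.sigma_ds,
        beta0=config.beta0,
        beta1=config.beta1,
        gamma=config.gamma,
        seed=config.seed,
    )
    return simulate_intensities(design, suite, noise)


@_stage("process")
def process_stage(config: RunConfig, intensities, design: ProbeDesign) -> list[BindingProfile]:
    return profiles_from_intensities(intensities, design, pool_flanks=config.pool_flanks)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest.

    Identical config + seed produces byte-identical outputs.  Artifacts:
    ``design.tsv``, ``intensities.tsv``, ``zscores.tsv``,
    ``correlations.tsv``, ``dendrogram.nwk``, ``heatmap.tsv``, per-protein
    barcode MEME + IC files, ``symmetry.tsv``, and ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    design = design_stage(config)
    write_design(design, outdir / "design.tsv")

    intensities = simulate_stage(config, design)
    write_intensities(intensities, outdir / "intensities.tsv")

    profiles = process_stage(config, intensities, design)
    write_zscore_table(profiles, outdir / "zscores.tsv")

    try:
        cm = correlation_matrix(profiles)
        write_correlations(cm, outdir / "correlations.tsv")
        dend = cluster_profiles(profiles, metric=config.metric)
        write_newick(dend, outdir / "dendrogram.nwk")
        hm, _, _ = heatmap_matrix(profiles, dend)
        hm.to_csv(outdir / "heatmap.tsv", sep="\t", lineterminator="\n",
                  float_format="%.6f")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'compare' failed: {exc}") from exc

    symmetry_rows = []
    try:
        width = len(design.cores[0]) if design.cores else 0
        for profile in profiles:
            top = top_n_probes(profile, design, n=min(config.top_n, profile.n_probes))
            barcode = position_frequency_matrix(top, protein=profile.protein)
            write_meme(barcode, outdir / f"barcode_{profile.protein}.meme")
            write_information_content(barcode, outdir / f"barcode_{profile.protein}_ic.tsv")
            if width == 11:
                symmetry_rows.append(
                    {"protein": profile.protein,
                     "half_site_symmetry": half_site_symmetry(barcode)}
                )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'barcode' failed: {exc}") from exc
    if symmetry_rows:
        import pandas as pd

        pd.DataFrame(symmetry_rows).to_csv(
            outdir / "symmetry.tsv", sep="\t", index=False, lineterminator="\n",
            float_format="%.6f",
        )

    outputs = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


@dataclass(frozen=True)
class FixtureBundle:
    design: ProbeDesign
    intensities: object  # pandas DataFrame
    profiles: tuple[BindingProfile, ...]


def make_fixtures(seed: int, outdir=None) -> FixtureBundle:
    """Miniature dataset: 32 cores x 2 flanks x 3 replicates, 4 proteins.

    Cores are selected by the full PCoA + k-medoids path from the 1,024-member
    10-mer space of the canonical consensus GGRRNNYYCC; regeneration with the
    same seed is byte-identical.
    """
    space = expand_iupac("GGRRNNYYCC")
    D = hamming_matrix(space)
    embedding = pcoa(D, retained_fraction=0.9)
    chosen = select_representatives(embedding, k=32, seed=seed)
    cores = [space.kmers[i] for i in chosen]
    design = assemble_probes(cores, DEFAULT_FLANKS[:2], replicates=3, capacity=15_000)
    noise = NoiseModel(seed=seed)
    intensities = simulate_intensities(design, default_dimer_suite(), noise)
    profiles = tuple(profiles_from_intensities(intensities, design))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_design(design, outdir / "design.tsv")
        write_intensities(intensities, outdir / "intensities.tsv")
        write_zscore_table(list(profiles), outdir / "zscores.tsv")
    return FixtureBundle(design=design, intensities=intensities, profiles=profiles)
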