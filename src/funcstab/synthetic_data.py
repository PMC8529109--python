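"""Synthetic soil-metagenome communities with tunable functional redundancy.

Generates :class:`~funcstab.io_profiles.LinkedProfile` objects whose
statistical structure mirrors what the downstream analysis assumes about
real soil shotgun-metagenome corpora:

* a long-tailed, geometrically decaying phylum abundance ranking with a
  few dominant phyla;
* genus-level diversity nested inside phyla (Dirichlet within-phylum
  composition);
* per-genus functional gene profiles that are a mixture of one shared
  "core" profile and a genus-specific profile, with the mixing weight
  ``redundancy`` controlling cross-taxon functional redundancy — at
  ``redundancy=1`` every genus encodes the same function mix, so removing
  taxa cannot change the relative functional profile;
* multiplicative log-normal sample-to-sample noise and Poisson counting
  noise.

The generative model is a fixed contract so tests can assert recovery of
the latent quantities exposed by :func:`ground_truth`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_profiles import COLUMNS, LinkedProfile

__all__ = ["SyntheticConfig", "GroundTruth", "generate_community", "ground_truth"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the community generator.

    Defaults describe a desk-scale soil-like corpus: 40 samples, 10 phyla
    with geometric rank-abundance decay 0.6 (top phylum ~40% of the
    community), 12 genera per phylum, 150 function categories, high
    functional redundancy (0.9), 50k expected hits per sample and moderate
    between-sample heterogeneity (log-normal sigma 0.5).
    """

    n_samples: int = 40
    n_phyla: int = 10
    genera_per_phylum: int = 12
    n_functions: int = 150
    redundancy: float = 0.9
    phylum_decay: float = 0.6
    depth: float = 50_000.0
    dispersion: float = 0.5
    seed: int = 0
    n_level1: int = 10  # function hierarchy width at the top level

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_phyla", "genera_per_phylum", "n_functions", "n_level1"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.redundancy <= 1.0:
            raise ValueError("redundancy must lie in [0, 1]")
        if not 0.0 < self.phylum_decay < 1.0:
            raise ValueError("phylum_decay must lie in (0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Latent quantities behind one generated community."""

    phylum_names: tuple[str, ...]  # descending expected abundance
    phylum_shares: np.ndarray  # (n_phyla,) sums to 1, strictly descending
    genus_names: tuple[str, ...]  # all genera, grouped by phylum rank
    genus_phylum: tuple[str, ...]  # phylum of each genus
    genus_shares: np.ndarray  # (n_genera,) global expected genus shares
    core_profile: np.ndarray  # (n_functions,)
    genus_profiles: np.ndarray  # (n_genera, n_functions), rows sum to 1
    function_names: tuple[str, ...]
    function_lineage: pd.DataFrame  # function, level1..level3


def _labels(config: SyntheticConfig):
    phyla = tuple(f"Phylum_{i + 1:02d}" for i in range(config.n_phyla))
    genera, genus_phylum = [], []
    for p_i, p in enumerate(phyla):
        for g_i in range(config.genera_per_phylum):
            genera.append(f"Genus_{p_i + 1:02d}_{g_i + 1:02d}")
            genus_phylum.append(p)
    functions = tuple(f"fn_{i + 1:04d}" for i in range(config.n_functions))
    # even nesting: level1 blocks split into two level2 blocks of two level3 blocks
    per_l1 = int(np.ceil(config.n_functions / config.n_level1))
    lineage = pd.DataFrame(
        {
            "function": functions,
            "level1": [f"L1_{i // per_l1 + 1:02d}" for i in range(config.n_functions)],
            "level2": [f"L2_{i // max(1, per_l1 // 2) + 1:03d}" for i in range(config.n_functions)],
            "level3": [f"L3_{i // max(1, per_l1 // 4) + 1:03d}" for i in range(config.n_functions)],
        }
    )
    return phyla, tuple(genera), tuple(genus_phylum), functions, lineage


def ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Latent phylum/genus composition and function profiles for ``config``.

    Uses the same RNG stream as :func:`generate_community`, so the returned
    quantities are exactly those behind the generated counts.
    """
    rng = np.random.default_rng(config.seed)
    phyla, genera, genus_phylum, functions, lineage = _labels(config)

    ranks = np.arange(config.n_phyla)
    shares = config.phylum_decay**ranks
    shares = shares / shares.sum()

    within = rng.dirichlet(np.ones(config.genera_per_phylum), size=config.n_phyla)
    genus_shares = (within * shares[:, None]).ravel()

    core = rng.dirichlet(np.full(config.n_functions, 0.5))
    specific = rng.dirichlet(
        np.full(config.n_functions, 0.5), size=len(genera)
    )
    profiles = config.redundancy * core[None, :] + (1.0 - config.redundancy) * specific

    return GroundTruth(
        phylum_names=phyla,
        phylum_shares=shares,
        genus_names=genera,
        genus_phylum=genus_phylum,
        genus_shares=genus_shares,
        core_profile=core,
        genus_profiles=profiles,
        function_names=functions,
        function_lineage=lineage,
    )


def generate_community(config: SyntheticConfig) -> LinkedProfile:
    """Draw one community; deterministic given ``config`` (incl. its seed).

    Per sample, genus abundances are perturbed by i.i.d. log-normal
    multiplicative factors and renormalized; counts for each
    (sample, genus, function) cell are Poisson with mean
    ``depth * genus_abundance * profile[genus, function]``. Zero cells are
    omitted from the long-format output.
    """
    truth = ground_truth(config)
    # independent child stream for the sampling noise, so the latent draws in
    # ground_truth stay aligned with the generated counts
    rng = np.random.default_rng([config.seed, 1])

    n_g = len(truth.genus_names)
    if config.dispersion > 0:
        noise = rng.lognormal(0.0, config.dispersion, size=(config.n_samples, n_g))
    else:
        noise = np.ones((config.n_samples, n_g))
    ab = truth.genus_shares[None, :] * noise
    ab = ab / ab.sum(axis=1, keepdims=True)

    mean = config.depth * ab[:, :, None] * truth.genus_profiles[None, :, :]
    counts = rng.poisson(mean)

    s_idx, g_idx, f_idx = np.nonzero(counts)
    lineage = truth.function_lineage
    sample_names = np.array([f"S{i + 1:03d}" for i in range(config.n_samples)])
    df = pd.DataFrame(
        {
            "sample": sample_names[s_idx],
            "genus": np.asarray(truth.genus_names)[g_idx],
            "phylum": np.asarray(truth.genus_phylum)[g_idx],
            "function": lineage["function"].to_numpy()[f_idx],
            "level1": lineage["level1"].to_numpy()[f_idx],
            "level2": lineage["level2"].to_numpy()[f_idx],
            "level3": lineage["level3"].to_numpy()[f_idx],
            "hits": counts[s_idx, g_idx, f_idx].astype(float),
        },
        columns=list(COLUMNS),
    )
    return LinkedProfile(df)
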