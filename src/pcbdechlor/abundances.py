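"""Synthetic genus-level relative-abundance tables with planted structure.

Stands in for a 16S amplicon genus table (samples x taxa, fractions
summing to 1 per sample).  Marginals are lognormal with per-taxon
parameters spanning several orders of magnitude, as genus abundances
do.  Correlated taxon blocks are planted through a Gaussian copula: a
shared latent factor with loadings chosen so each within-block pair
attains a target Spearman correlation (rank correlations survive the
monotone lognormal transform; the sign pattern follows per-taxon
loadings).  Group effects (treatment x origin layouts such as
Bla/HM/HA/AQDS x M/T) enter as multiplicative shifts before closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PlantedBlock", "GroupEffect", "AbundanceSpec", "simulate_abundances"]


def _latent_corr(spearman: float) -> float:
    """Gaussian-copula correlation achieving a target Spearman rho."""
    return 2.0 * np.sin(np.pi * spearman / 6.0)


@dataclass(frozen=True)
class PlantedBlock:
    """A set of taxa sharing one latent factor.

    ``spearman`` in (-1, 1) is the target pairwise Spearman strength;
    ``signs`` (+1/-1 per taxon, default all +1) set which taxa load
    positively vs negatively, so mixed-sign blocks plant negative
    pairwise correlations.
    """

    taxa: tuple
    spearman: float
    signs: tuple | None = None

    def __post_init__(self):
        if not -1.0 < self.spearman < 1.0:
            raise ValueError(f"block strength must be in (-1, 1), got {self.spearman}")
        if self.signs is not None and len(self.signs) != len(self.taxa):
            raise ValueError("signs must match the block's taxa")

    def sign_vector(self) -> np.ndarray:
        if self.signs is None:
            return np.ones(len(self.taxa))
        return np.asarray(self.signs, dtype=float)


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative abundance shift of one taxon in one sample group."""

    taxon: str
    group: str
    multiplier: float


@dataclass(frozen=True)
class AbundanceSpec:
    """Layout and statistical parameters of the abundance generator.

    ``groups`` maps group name to number of replicate samples (the
    study layout is 4 treatments x 3 replicates per origin).  Lognormal
    marginal parameters are drawn per taxon from ``mu_sd`` /
    ``sigma_range`` so realized relative abundances span realistic
    orders of magnitude.
    """

    n_taxa: int = 120
    groups: dict = field(
        default_factory=lambda: {"Bla": 3, "HM": 3, "HA": 3, "AQDS": 3}
    )
    blocks: tuple = ()
    group_effects: tuple = ()
    mu_sd: float = 1.0
    sigma_range: tuple = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1 or not self.groups:
            raise ValueError("need at least one taxon and one sample group")
        names = set(self.taxon_names)
        for block in self.blocks:
            unknown = set(block.taxa) - names
            if unknown:
                raise ValueError(f"block references unknown taxa {sorted(unknown)}")
        claimed: set = set()
        for block in self.blocks:
            overlap = claimed & set(block.taxa)
            if overlap:
                raise ValueError(f"taxa {sorted(overlap)} appear in multiple blocks")
            claimed |= set(block.taxa)
        for eff in self.group_effects:
            if eff.taxon not in names:
                raise ValueError(f"group effect references unknown taxon {eff.taxon!r}")
            if eff.group not in self.groups:
                raise ValueError(f"group effect references unknown group {eff.group!r}")

    @property
    def taxon_names(self) -> tuple:
        return tuple(f"g{i:03d}" for i in range(self.n_taxa))

    @property
    def sample_names(self) -> tuple:
        return tuple(
            f"{group}-{i + 1}" for group, n in self.groups.items() for i in range(n)
        )


def simulate_abundances(spec: AbundanceSpec, return_meta: bool = False):
    """Generate a samples x taxa relative-abundance table.

    Deterministic for a given spec (all randomness flows from
    ``spec.seed``).  With ``return_meta=True`` also returns generator
    bookkeeping: sample->group mapping, the planted within-block pairs
    with their target signs, and the pre-closure expected mean
    abundance of each taxon.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = spec.taxon_names
    samples = spec.sample_names
    n_s, n_t = len(samples), len(taxa)

    mu = rng.normal(0.0, spec.mu_sd, size=n_t)
    sigma = rng.uniform(*spec.sigma_range, size=n_t)

    z = rng.standard_normal((n_s, n_t))
    for block in spec.blocks:
        rho = _latent_corr(abs(block.spearman))
        loading = np.sqrt(rho)
        factor = rng.standard_normal(n_s)
        signs = block.sign_vector() * np.sign(block.spearman)
        for taxon, s in zip(block.taxa, signs):
            j = taxa.index(taxon)
            z[:, j] = s * loading * factor + np.sqrt(1.0 - rho) * z[:, j]

    x = np.exp(mu + sigma * z)

    group_of = {}
    for name in samples:
        group_of[name] = name.rsplit("-", 1)[0]
    for eff in spec.group_effects:
        j = taxa.index(eff.taxon)
        rows = [i for i, s in enumerate(samples) if group_of[s] == eff.group]
        x[rows, j] *= eff.multiplier

    x = x / x.sum(axis=1, keepdims=True)
    table = pd.DataFrame(x, index=pd.Index(samples, name="sample"), columns=taxa)
    if not return_meta:
        return table

    planted_pairs = []
    for block in spec.blocks:
        signs = block.sign_vector() * np.sign(block.spearman)
        for (a, sa), (b, sb) in _pairs(list(zip(block.taxa, signs))):
            planted_pairs.append((a, b, float(sa * sb * abs(block.spearman))))
    meta = {
        "group_of": group_of,
        "planted_pairs": planted_pairs,
        "lognormal_mu": dict(zip(taxa, mu)),
        "lognormal_sigma": dict(zip(taxa, sigma)),
    }
    return table, meta


def _pairs(items):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]
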