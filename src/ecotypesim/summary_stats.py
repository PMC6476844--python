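"""Differentiation and genome-content statistics.

Phenotypic divergence is the absolute difference of subpopulation mean
phenotypes.  Per-locus genetic divergence compares only each
subpopulation's most frequent ("leading") allele: ``d = |a1 - a2|``,
summarized over loci as ``d_max`` and ``d_mean``.  In scenarios with
gene loss, an absent slot counts as a vote for a virtual allele of
effect zero, which can itself be the leading allele of a mostly-lost
locus.  Genome-content statistics count missing slots, extant loci,
copies per surviving locus, and loci private to one subpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import PopulationState

__all__ = [
    "DivergenceProfile",
    "GenomeContentStats",
    "phenotypic_divergence",
    "leading_allele",
    "divergence_profile",
    "genome_content",
]


@dataclass
class DivergenceProfile:
    """Per-locus leading-allele divergences with their summaries.

    ``d`` is in locus order; ``sorted_d`` (descending) matches the
    convention of plotting loci from largest to smallest divergence.
    ``d_mean`` averages over all L loci, including extinct ones.
    """

    d: np.ndarray
    leading_pop1: np.ndarray
    leading_pop2: np.ndarray

    @property
    def d_max(self) -> float:
        return float(self.d.max())

    @property
    def d_mean(self) -> float:
        return float(self.d.mean())

    @property
    def sorted_d(self) -> np.ndarray:
        return np.sort(self.d)[::-1]


@dataclass
class GenomeContentStats:
    pct_missing: float
    n_extant_loci: int
    copies_per_surviving_locus: float
    private_locus_fraction: float


def _require_split(state: PopulationState) -> None:
    if not state.is_split:
        raise ValueError("statistic requires a post-split population")
    if not (state.niche_of == 0).any() or not (state.niche_of == 1).any():
        raise ValueError("both subpopulations must be non-empty")


def phenotypic_divergence(state: PopulationState) -> float:
    """``|mean phenotype of subpopulation 1 - mean phenotype of subpopulation 2|``."""
    _require_split(state)
    phen = state.phenotypes()
    return float(abs(phen[state.niche_of == 0].mean() - phen[state.niche_of == 1].mean()))


def leading_allele(
    state: PopulationState,
    locus: int,
    subpop: int,
    absence_as_zero: bool = False,
) -> float:
    """Most frequent allele effect at ``locus`` within one subpopulation.

    Alleles are identified by exact effect value (identity by copying;
    under the evolving model mutation almost surely creates new values).
    With ``absence_as_zero`` each absent slot votes for a virtual allele
    of effect 0.0 — appropriate for scenarios with gene loss, where
    absence itself can be the leading state.  Ties are broken toward the
    smallest effect value, deterministically.  A locus with no copies
    (and no absence votes requested) has a leading effect of 0.0.
    """
    rows = state.niche_of == subpop
    here = rows & state.present[:, locus]
    values = state.effects[here, locus]
    uniq, counts = np.unique(values, return_counts=True)
    if absence_as_zero:
        n_absent = int(rows.sum() - here.sum())
        if n_absent > 0:
            at_zero = np.searchsorted(uniq, 0.0)
            if at_zero < uniq.size and uniq[at_zero] == 0.0:
                counts[at_zero] += n_absent
            else:
                uniq = np.insert(uniq, at_zero, 0.0)
                counts = np.insert(counts, at_zero, n_absent)
    if uniq.size == 0:
        return 0.0
    # np.unique sorts ascending, so argmax lands on the smallest tied value
    return float(uniq[np.argmax(counts)])


def divergence_profile(state: PopulationState, absence_as_zero: bool = False) -> DivergenceProfile:
    """Per-locus ``d = |a1 - a2|`` between subpopulation leading alleles."""
    _require_split(state)
    L = state.n_loci
    a1 = np.array([leading_allele(state, l, 0, absence_as_zero) for l in range(L)])
    a2 = np.array([leading_allele(state, l, 1, absence_as_zero) for l in range(L)])
    return DivergenceProfile(d=np.abs(a1 - a2), leading_pop1=a1, leading_pop2=a2)


def genome_content(state: PopulationState, private_threshold: float = 0.95) -> GenomeContentStats:
    """Genome-content summaries of a (possibly loss-affected) population.

    ``pct_missing`` is the mean over individuals of the percentage of
    their slots that are absent.  A locus is extant if at least one copy
    survives anywhere in the metapopulation; ``copies_per_surviving_locus``
    averages the extant-copy counts over extant loci (NaN if none remain).
    A locus is private when its presence frequency is at least
    ``private_threshold`` in one subpopulation and at most
    ``1 - private_threshold`` in the other — a near-fixation criterion for
    being effectively restricted to a single subpopulation.
    """
    if not 0.5 < private_threshold <= 1.0:
        raise ValueError("private_threshold must lie in (0.5, 1]")
    _require_split(state)
    present = state.present
    L = state.n_loci
    pct_missing = 100.0 * float((~present).mean())
    copies = present.sum(axis=0)
    extant = copies > 0
    n_extant = int(extant.sum())
    mean_copies = float(copies[extant].mean()) if n_extant else float("nan")
    f1 = present[state.niche_of == 0].mean(axis=0)
    f2 = present[state.niche_of == 1].mean(axis=0)
    lo = 1.0 - private_threshold
    private = ((f1 >= private_threshold) & (f2 <= lo)) | ((f2 >= private_threshold) & (f1 <= lo))
    return GenomeContentStats(
        pct_missing=pct_missing,
        n_extant_loci=n_extant,
        copies_per_surviving_locus=mean_copies,
        private_locus_fraction=float(private.sum()) / L,
    )
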