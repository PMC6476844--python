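"""Core types of the two-niche bacterial divergence model.

The model follows a single quantitative trait in a haploid population of
``N`` cells split (after a burn-in) into two subpopulations of ``N/2``,
each adapting to its own phenotypic optimum.  An individual's genome is a
row of ``L`` locus slots; each present slot carries a real-valued allele
effect size and the phenotype is the plain sum of effects over present
slots (additive, no environmental variance).  Absent slots contribute
zero and are exempt from mutation and homologous recombination.

Fitness is Gaussian stabilizing selection around the niche optimum::

    W(p) = exp(-(p - x)^2 / (2 * sigma_w^2))

Cells never migrate between niches; DNA may, depending on the gene-pool
scope chosen for homologous recombination and gene gain.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "ScenarioConfig",
    "PopulationState",
    "fitness",
    "phenotype",
    "founder_population",
    "save_snapshot",
    "load_snapshot",
]

EFFECT_MODELS = ("fixed", "evolving")
GENE_POOLS = ("global", "local")
SELECTION_MODES = ("neutral", "divergent")
SURVIVAL_MODELS = ("fitness_weighted", "fitness_ranked")
BURN_IN_PROCESSES = ("all", "mutation_only")

#: niche label of individuals before the population is split
UNSPLIT = -1


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete parameterization of one simulation scenario.

    Parameters mirror the model's rate and selection constants: all rates
    are per extant gene copy (or per empty slot for ``gain_rate``) per
    generation, interpreted as independent Bernoulli event probabilities.

    Attributes
    ----------
    n_total:
        Metapopulation size ``N`` (even); each subpopulation holds ``N/2``.
    n_loci:
        Number of locus slots ``L`` per genome.
    mutation_rate:
        Per-copy mutation probability ``m`` per generation.
    recombination_rate:
        Per-copy homologous-recombination (gene conversion) probability ``r``.
    loss_rate, gain_rate:
        Per-copy gene-loss probability ``lambda`` and per-empty-slot gene-gain
        probability ``gamma``.  Gain only refills lost slots, so it requires
        ``loss_rate > 0``.
    sigma2_mutation:
        Variance of the Gaussian mutation kernel under ``effect_model="evolving"``.
    sigma2_selection:
        Width ``sigma_w^2`` of the stabilizing-selection function; larger is
        weaker selection.
    optima:
        Pair of niche phenotypic optima ``(x1, x2)``.
    effect_model:
        ``"fixed"`` (two alleles ``+a``/``-a`` with symmetric mutation) or
        ``"evolving"`` (continuous effects, Gaussian mutation kernel).
    gene_pool:
        Donor scope for recombination and gain: ``"global"`` (whole
        metapopulation) or ``"local"`` (recipient's own subpopulation).
    selection:
        ``"divergent"`` (fitness-weighted survival toward each niche optimum)
        or ``"neutral"`` (uniform survival).
    allele_magnitude:
        Fixed-model allele size ``a``; defaults to ``|x1| / L`` so that a
        full complement of ``+a`` alleles is optimal in niche 1.
    survival_model:
        How the surviving half of the offspring pool is chosen under
        divergent selection.  ``"fitness_weighted"`` (default): sequential
        draws without replacement with probability proportional to fitness.
        ``"fitness_ranked"``: the fittest half survives deterministically,
        ties resolved uniformly at random — a much stronger selection
        regime that pins populations to their optima.
    burn_in_processes:
        ``"all"`` (default): the burn-in runs every configured operator
        (mutation, recombination, loss, gain) with neutral reproduction —
        a single generation loop in which only selection is phase-dependent.
        ``"mutation_only"``: recombination, loss and gain start at the split.
    track_lineage:
        Tag every gene copy with the subpopulation it occupied at the split
        and propagate tags through copying; used to audit gene-flow isolation.
    """

    n_total: int = 2000
    n_loci: int = 10
    mutation_rate: float = 0.005
    recombination_rate: float = 0.0
    loss_rate: float = 0.0
    gain_rate: float = 0.0
    sigma2_mutation: float = 0.0004
    sigma2_selection: float = 2.0
    optima: tuple[float, float] = (1.0, -1.0)
    effect_model: str = "fixed"
    gene_pool: str = "global"
    selection: str = "divergent"
    burn_in_generations: int = 1000
    run_generations: int = 5000
    record_every: int = 10
    seed: int = 0
    allele_magnitude: Optional[float] = None
    survival_model: str = "fitness_weighted"
    burn_in_processes: str = "all"
    track_lineage: bool = False
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if self.n_total < 2 or self.n_total % 2:
            raise ValueError(f"n_total must be even and >= 2, got {self.n_total}")
        if self.n_loci < 1:
            raise ValueError(f"n_loci must be >= 1, got {self.n_loci}")
        for name in ("mutation_rate", "recombination_rate", "loss_rate", "gain_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma2_selection <= 0:
            raise ValueError("sigma2_selection must be positive")
        if self.sigma2_mutation < 0:
            raise ValueError("sigma2_mutation must be non-negative")
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(f"effect_model must be one of {EFFECT_MODELS}")
        if self.gene_pool not in GENE_POOLS:
            raise ValueError(f"gene_pool must be one of {GENE_POOLS}")
        if self.selection not in SELECTION_MODES:
            raise ValueError(f"selection must be one of {SELECTION_MODES}")
        if self.survival_model not in SURVIVAL_MODELS:
            raise ValueError(f"survival_model must be one of {SURVIVAL_MODELS}")
        if self.burn_in_processes not in BURN_IN_PROCESSES:
            raise ValueError(f"burn_in_processes must be one of {BURN_IN_PROCESSES}")
        if self.gain_rate > 0 and self.loss_rate == 0:
            # the model starts with the maximum locus complement, so gain
            # can only ever refill slots opened by loss
            raise ValueError("gain_rate > 0 requires loss_rate > 0")
        if len(self.optima) != 2:
            raise ValueError("optima must be a pair (x1, x2)")
        if self.burn_in_generations < 0 or self.run_generations < 0:
            raise ValueError("generation counts must be non-negative")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        object.__setattr__(self, "optima", tuple(float(x) for x in self.optima))

    @property
    def n_sub(self) -> int:
        """Subpopulation size ``N/2``."""
        return self.n_total // 2

    @property
    def allele_size(self) -> float:
        """Fixed-model allele magnitude ``a`` (``|x1| / L`` unless overridden)."""
        if self.allele_magnitude is not None:
            return float(self.allele_magnitude)
        return abs(self.optima[0]) / self.n_loci

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["optima"] = list(self.optima)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {', '.join(unknown)}")
        data = dict(data)
        if "optima" in data:
            data["optima"] = tuple(data["optima"])
        return cls(**data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ScenarioConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("configuration file must contain a key-value mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PopulationState:
    """The complete evolving state: effects, presence, niche assignment.

    ``effects[i, l]`` is the allele effect size carried by individual ``i``
    at locus ``l``; entries where ``present`` is False are kept at exactly
    0.0 and contribute nothing to the phenotype.  ``niche_of`` is -1 for
    every individual before the split, afterwards 0 or 1 (fixed; cells do
    not migrate).  ``origin`` optionally tags each gene copy with the
    subpopulation its lineage occupied at the split (-1 = untagged/absent).
    """

    effects: np.ndarray
    present: np.ndarray
    niche_of: np.ndarray
    generation: int = 0
    origin: Optional[np.ndarray] = None

    @property
    def n_individuals(self) -> int:
        return self.effects.shape[0]

    @property
    def n_loci(self) -> int:
        return self.effects.shape[1]

    @property
    def is_split(self) -> bool:
        return bool(np.all(self.niche_of >= 0))

    def phenotypes(self) -> np.ndarray:
        """Additive phenotype of every individual (absent slots are zero)."""
        return (self.effects * self.present).sum(axis=1)

    def subpop_rows(self, which: int) -> np.ndarray:
        """Row indices of subpopulation ``which`` (0 or 1)."""
        return np.flatnonzero(self.niche_of == which)

    def copy(self) -> "PopulationState":
        return PopulationState(
            effects=self.effects.copy(),
            present=self.present.copy(),
            niche_of=self.niche_of.copy(),
            generation=self.generation,
            origin=None if self.origin is None else self.origin.copy(),
        )


def fitness(p, x: float, sigma2_w: float):
    """Stabilizing-selection fitness ``W(p) = exp(-(p-x)^2 / (2 sigma_w^2))``.

    Maximal (1.0) at the optimum ``x``, symmetric about it, and strictly
    decreasing in ``|p - x|``.  Accepts scalars or arrays of phenotypes.
    """
    if sigma2_w <= 0:
        raise ValueError("sigma2_w must be positive")
    p = np.asarray(p, dtype=float)
    w = np.exp(-((p - x) ** 2) / (2.0 * sigma2_w))
    return w if w.ndim else float(w)

def phenotype(effects_row, present_row) -> float:
    """Sum of effect sizes over present loci of one individual."""
    effects_row = np.asarray(effects_row, dtype=float)
    present_row = np.asarray(present_row, dtype=bool)
    if effects_row.shape != present_row.shape:
        raise ValueError("effects and presence rows must have equal length")
    return float(effects_row[present_row].sum())


def founder_population(config: ScenarioConfig) -> PopulationState:
    """Fully homogeneous founders, optimal for niche 1.

    Every individual carries all ``L`` loci, each with effect ``x1 / L``,
    so every founder phenotype equals the niche-1 optimum exactly.  Under
    the fixed model this founder allele is ``+a`` (``a = |x1|/L``).
    """
    n, l = config.n_total, config.n_loci
    value = config.optima[0] / l
    state = PopulationState(
        effects=np.full((n, l), value, dtype=float),
        present=np.ones((n, l), dtype=bool),
        niche_of=np.full(n, UNSPLIT, dtype=np.int8),
        generation=0,
        origin=np.full((n, l), -1, dtype=np.int8) if config.track_lineage else None,
    )
    return state


# -- snapshot container ------------------------------------------------

_SNAPSHOT_VERSION = 1


def save_snapshot(path: str | Path, state: PopulationState, config: ScenarioConfig) -> None:
    """Write a resumable population snapshot (NumPy ``.npz`` container).

    Stores the full state matrices plus the generation index, the scenario
    configuration (as JSON) and its hash, so a long run can be resumed or
    inspected with exact provenance.
    """
    arrays = {
        "effects": state.effects,
        "present": state.present,
        "niche_of": state.niche_of,
        "generation": np.asarray(state.generation, dtype=np.int64),
        "config_json": np.asarray(json.dumps(config.to_dict(), sort_keys=True)),
        "config_hash": np.asarray(config.config_hash()),
        "snapshot_version": np.asarray(_SNAPSHOT_VERSION, dtype=np.int64),
    }
    if state.origin is not None:
        arrays["origin"] = state.origin
    np.savez_compressed(path, **arrays)


def load_snapshot(path: str | Path) -> tuple[PopulationState, ScenarioConfig]:
    """Read a snapshot written by :func:`save_snapshot`."""
    try:
        with np.load(path, allow_pickle=False) as data:
            config = ScenarioConfig.from_dict(json.loads(str(data["config_json"])))
            stored_hash = str(data["config_hash"])
            if config.config_hash() != stored_hash:
                raise ValueError("snapshot config hash mismatch (corrupt snapshot?)")
            state = PopulationState(
                effects=np.array(data["effects"], dtype=float),
                present=np.array(data["present"], dtype=bool),
                niche_of=np.array(data["niche_of"], dtype=np.int8),
                generation=int(data["generation"]),
                origin=np.array(data["origin"], dtype=np.int8) if "origin" in data else None,
            )
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read population snapshot {path!r}: {exc}") from exc
    if state.effects.shape != state.present.shape or state.effects.shape[0] != state.niche_of.shape[0]:
        raise ValueError("snapshot arrays have inconsistent shapes")
    return state, config
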