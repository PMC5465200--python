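"""Synthetic datasets with the structure the analysis pipeline assumes.

Two generators are provided:

* :func:`simulate_clan` — descendants of a founder 15-locus haplotype under
  the symmetric single-step mutation model, either as a star genealogy
  (each sampled lineage accumulates Poisson(mu * depth) mutations per
  locus, each +/-1 with probability 1/2) or as a discrete-generation
  Galton-Watson branching process.

* :func:`simulate_populations` — grouped populations whose haplogroup
  frequencies are Dirichlet draws around group means, themselves Dirichlet
  draws around a base vector; a low concentration produces strong
  between-group divergence, a huge one the null of no structure.

Both record ground truth sufficient to replay every emitted haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ystr.data_io import (
    ALLELE_MIN,
    STR_LOCI_15,
    PopulationMeta,
    SampleRecord,
    StrHaplotype,
)
from ystr.tmrca import MutationModelParams

#: Founder profiles typical of Central Asian descent clusters; the first is
#: the default simulator founder.  Keys are informal cluster names.
EXAMPLE_FOUNDERS: dict[str, StrHaplotype] = {
    "alpha": StrHaplotype(
        alleles=(14, 17, 25, 15, 16, 17, 14, 10, 20, 10, 10, 11, 13, 11, 23),
        haplogroup="C2b1a2-M48",
    ),
    "sigma": StrHaplotype(
        alleles=(14, 15, 23, 15, 15, 18, 14, 10, 21, 11, 10, 11, 14, 12, 21),
        haplogroup="C2*-M217(xM48)",
    ),
    "mu": StrHaplotype(
        alleles=(13, 16, 25, 15, 16, 18, 14, 10, 22, 11, 10, 11, 13, 10, 21),
        haplogroup="C2*-M217(xM48)",
    ),
    "delta": StrHaplotype(
        alleles=(13, 15, 23, 17, 13, 19, 14, 11, 22, 11, 10, 16, 13, 13, 23),
        haplogroup="Q-M242",
    ),
}

DEFAULT_FOUNDER = EXAMPLE_FOUNDERS["alpha"]


@dataclass
class ClanSimConfig:
    n_samples: int
    depth_generations: float
    genealogy: str = "star"  # star | galton_watson
    offspring_mean: float = 1.2  # galton_watson only
    params: MutationModelParams = field(default_factory=MutationModelParams)
    founder: StrHaplotype = DEFAULT_FOUNDER
    haplogroup_label: Optional[str] = None
    population_code: str = "SIM1"
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.depth_generations <= 0:
            raise ValueError("depth must be positive")
        if self.genealogy not in ("star", "galton_watson"):
            raise ValueError(f"unknown genealogy {self.genealogy!r}")
        if (self.genealogy == "galton_watson"
                and self.depth_generations != int(self.depth_generations)):
            raise ValueError("galton_watson mode needs integer generations")


@dataclass
class PopulationSimConfig:
    n_groups: int
    pops_per_group: int
    samples_per_pop: int
    haplogroup_labels: list[str]
    base_frequencies: Sequence[float]
    concentration: float = 10.0  # between-group Dirichlet concentration
    within_group_concentration: float = 200.0
    coordinate_box: tuple[float, float, float, float] = (38.0, 46.0, 56.0, 70.0)
    spatially_segregated: bool = False
    scheme_name: str = "sim_group"
    seed: int = 0

    def __post_init__(self) -> None:
        base = np.asarray(self.base_frequencies, dtype=float)
        if len(base) != len(self.haplogroup_labels):
            raise ValueError("base frequencies must match haplogroup labels")
        if not np.isclose(base.sum(), 1.0, atol=1e-9):
            raise ValueError("base frequencies must sum to 1")
        if self.concentration <= 0 or self.within_group_concentration <= 0:
            raise ValueError("concentrations must be positive")


@dataclass
class TruthRecord:
    """Ground truth emitted next to simulated data.

    ``mutations`` maps sample id to an ordered list of (locus index, step)
    events; replaying them from the founder reproduces the haplotype.
    """

    true_tmrca_years: Optional[float] = None
    genealogy: dict[str, Optional[str]] = field(default_factory=dict)
    mutations: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    branch_mutation_counts: dict[str, int] = field(default_factory=dict)
    group_frequencies: Optional[dict[str, list[float]]] = None


def _apply_steps(
    allele: int, k: int, rng: np.random.Generator
) -> tuple[int, list[int]]:
    """Apply k single steps with the floor-at-ALLELE_MIN redraw rule."""
    steps = []
    for _ in range(k):
        step = 1 if rng.random() < 0.5 else -1
        if allele <= ALLELE_MIN and step == -1:
            step = 1  # downward mutation at the floor redrawn upward
        allele += step
        steps.append(step)
    return allele, steps


def simulate_clan(
    cfg: ClanSimConfig,
) -> tuple[list[StrHaplotype], TruthRecord]:
    """Simulate descendants of a founder haplotype under single-step SMM."""
    rng = np.random.default_rng(cfg.seed)
    params = cfg.params
    label = cfg.haplogroup_label or cfg.founder.haplogroup
    founder_alleles = cfg.founder.alleles
    n_loci = len(founder_alleles)
    truth = TruthRecord(
        true_tmrca_years=cfg.depth_generations * params.generation_years
    )
    haplotypes: list[StrHaplotype] = []

    if cfg.genealogy == "star":
        lam = params.mu * cfg.depth_generations
        k_matrix = rng.poisson(lam, size=(cfg.n_samples, n_loci))
        for i in range(cfg.n_samples):
            sid = f"S{i:05d}"
            truth.genealogy[sid] = None  # direct founder descendant
            alleles = list(founder_alleles)
            events: list[tuple[int, int]] = []
            for locus in np.nonzero(k_matrix[i])[0]:
                new, steps = _apply_steps(
                    alleles[locus], int(k_matrix[i, locus]), rng
                )
                alleles[locus] = new
                events.extend((int(locus), s) for s in steps)
            truth.mutations[sid] = events
            truth.branch_mutation_counts[sid] = len(events)
            haplotypes.append(
                StrHaplotype(alleles=tuple(alleles), haplogroup=label)
            )
        return haplotypes, truth

    # Galton-Watson branching, conditioned on >= n_samples survivors
    depth = int(cfg.depth_generations)
    for attempt in range(cfg.max_retries):
        lineages = [("root", list(founder_alleles), [])]
        genealogy: dict[str, Optional[str]] = {"root": None}
        mutations: dict[str, list[tuple[int, int]]] = {"root": []}
        counter = 0
        ok = True
        for _ in range(depth):
            nxt = []
            for name, alleles, _events in lineages:
                for _ in range(rng.poisson(cfg.offspring_mean)):
                    child = f"L{counter:06d}"
                    counter += 1
                    child_alleles = list(alleles)
                    events: list[tuple[int, int]] = []
                    hits = np.nonzero(rng.random(n_loci) < params.mu)[0]
                    for locus in hits:
                        new, steps = _apply_steps(
                            child_alleles[locus], 1, rng
                        )
                        child_alleles[locus] = new
                        events.extend((int(locus), s) for s in steps)
                    genealogy[child] = name
                    mutations[child] = events
                    nxt.append((child, child_alleles, events))
            if not nxt or len(nxt) > 200_000:
                ok = False
                break
            lineages = nxt
        if ok and len(lineages) >= cfg.n_samples:
            pick = rng.choice(len(lineages), size=cfg.n_samples, replace=False)
            truth.genealogy = genealogy
            for idx in sorted(pick):
                name, alleles, _ = lineages[idx]
                truth.mutations[name] = _full_event_path(
                    name, genealogy, mutations
                )
                truth.branch_mutation_counts[name] = len(mutations[name])
                haplotypes.append(
                    StrHaplotype(alleles=tuple(alleles), haplogroup=label)
                )
            return haplotypes, truth
    raise RuntimeError(
        f"galton_watson simulation failed to reach n={cfg.n_samples} "
        f"survivors after {cfg.max_retries} retries"
    )


def _full_event_path(name, genealogy, mutations) -> list[tuple[int, int]]:
    chain = []
    cur = name
    while cur is not None and cur in mutations:
        chain.append(mutations[cur])
        cur = genealogy.get(cur)
    events: list[tuple[int, int]] = []
    for branch in reversed(chain):
        events.extend(branch)
    return events


def replay_truth(
    truth: TruthRecord, founder: StrHaplotype
) -> dict[str, tuple[int, ...]]:
    """Reconstruct haplotype profiles from recorded mutation events."""
    out = {}
    for sid, events in truth.mutations.items():
        alleles = list(founder.alleles)
        for locus, step in events:
            alleles[locus] += step
        out[sid] = tuple(alleles)
    return out


def clan_to_records(
    haplotypes: Sequence[StrHaplotype],
    cfg: ClanSimConfig,
    snp_calls: Optional[dict[str, str]] = None,
) -> list[SampleRecord]:
    """Express simulated haplotypes as raw sample-table records.

    DYS389II is rebuilt as DYS389I + DYS389b; DYS385a/b get fixed filler
    alleles (they are excluded from all analyses anyway).
    """
    records = []
    for i, h in enumerate(haplotypes):
        raw = {}
        for locus, allele in zip(STR_LOCI_15, h.alleles):
            if locus == "DYS389b":
                raw["DYS389II"] = h.alleles[0] + allele
            else:
                raw[locus] = allele
        raw["DYS385a"], raw["DYS385b"] = 12, 12
        records.append(
            SampleRecord(
                sample_id=f"S{i:05d}",
                population_code=cfg.population_code,
                snp_calls=dict(snp_calls or {}),
                str_raw=raw,
            )
        )
    return records


def _snp_calls_for_label(label: str) -> dict[str, str]:
    """Derived calls along the tree path that reproduce ``label``."""
    from ystr.haplogroups import default_tree

    tree = default_tree()
    for marker, node in tree.nodes.items():
        if node.label == label:
            calls = {marker: "derived"}
            for anc in tree.ancestors(marker):
                calls[anc] = "derived"
            return calls
    return {}


def simulate_populations(
    cfg: PopulationSimConfig,
) -> tuple[list[SampleRecord], list[PopulationMeta], TruthRecord]:
    """Simulate grouped populations with divergent haplogroup frequencies."""
    rng = np.random.default_rng(cfg.seed)
    base = np.asarray(cfg.base_frequencies, dtype=float)
    base = np.clip(base, 1e-9, None)
    base /= base.sum()
    lat_min, lat_max, lon_min, lon_max = cfg.coordinate_box

    records: list[SampleRecord] = []
    metas: list[PopulationMeta] = []
    truth = TruthRecord(group_frequencies={})
    snp_by_label = {lab: _snp_calls_for_label(lab)
                    for lab in cfg.haplogroup_labels}
    sample_idx = 0
    for g in range(cfg.n_groups):
        group_label = f"G{g + 1}"
        group_freq = rng.dirichlet(cfg.concentration * base)
        truth.group_frequencies[group_label] = group_freq.tolist()
        if cfg.spatially_segregated:
            slab = (lon_max - lon_min) / cfg.n_groups
            g_lon_min, g_lon_max = lon_min + g * slab, lon_min + (g + 1) * slab
        else:
            g_lon_min, g_lon_max = lon_min, lon_max
        for p in range(cfg.pops_per_group):
            pop_code = f"{group_label}P{p + 1}"
            alpha = np.clip(
                cfg.within_group_concentration * group_freq, 1e-9, None
            )
            pop_freq = rng.dirichlet(alpha)
            metas.append(
                PopulationMeta(
                    population_code=pop_code,
                    group_labels={cfg.scheme_name: group_label},
                    latitude=float(rng.uniform(lat_min, lat_max)),
                    longitude=float(rng.uniform(g_lon_min, g_lon_max)),
                )
            )
            draws = rng.choice(
                len(cfg.haplogroup_labels),
                size=cfg.samples_per_pop,
                p=pop_freq,
            )
            for d in draws:
                label = cfg.haplogroup_labels[int(d)]
                records.append(
                    SampleRecord(
                        sample_id=f"P{sample_idx:05d}",
                        population_code=pop_code,
                        snp_calls=dict(snp_by_label[label]),
                        haplogroup=label,
                    )
                )
                sample_idx += 1
    return records, metas, truth
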