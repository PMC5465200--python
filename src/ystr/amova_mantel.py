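"""Three-level AMOVA on haplogroup assignments and the Mantel test.

The molecular distance between two individuals is 0 if they carry the same
haplogroup and 1 otherwise, so all sums of squares reduce to haplogroup
count vectors: for a set of m samples with class counts c,
SS = (m^2 - sum c^2) / (2 m).  Variance components follow the Excoffier
nested design with unequal sample sizes; negative components are retained
(Arlequin convention) and percentages always total 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ystr.data_io import SampleRecord
from ystr.popgen_distance import DistanceMatrix


@dataclass
class GroupingScheme:
    """Assignment of populations to named groups (e.g. settled vs nomadic)."""

    name: str
    assignment: dict[str, str]  # population -> group label

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pop in sorted(self.assignment):
            out.setdefault(self.assignment[pop], []).append(pop)
        return out


@dataclass
class AmovaResult:
    sigma2: tuple[float, float, float]  # (among groups, among pops, within)
    pct_among_groups: float
    pct_among_populations_within_groups: float
    pct_within_populations: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_values: dict[str, float]  # keys phi_ct, phi_sc, phi_st
    n_permutations: int
    no_variation: bool = False
    scheme: str = ""
    seed: Optional[int] = None


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: Optional[int] = None


def _ss_from_counts(counts: np.ndarray) -> float:
    """Sum of squared 0/1 distances within a set, divided by its size."""
    m = counts.sum()
    if m == 0:
        return 0.0
    return float((m * m - np.sum(counts.astype(float) ** 2)) / (2.0 * m))


def _components(
    pop_counts: np.ndarray,  # (n_pops, n_classes)
    group_of: np.ndarray,  # group index per population
    n_groups: int,
) -> tuple[float, float, float]:
    """Excoffier variance components (sigma_a, sigma_b, sigma_c)."""
    n_pops = pop_counts.shape[0]
    pop_sizes = pop_counts.sum(axis=1).astype(float)
    n_total = float(pop_sizes.sum())

    ss_wp = sum(_ss_from_counts(pop_counts[i]) for i in range(n_pops))
    group_counts = np.zeros((n_groups, pop_counts.shape[1]))
    for i in range(n_pops):
        group_counts[group_of[i]] += pop_counts[i]
    ss_groups = sum(_ss_from_counts(group_counts[g]) for g in range(n_groups))
    ss_total = _ss_from_counts(pop_counts.sum(axis=0))

    ss_b = ss_groups - ss_wp  # among populations within groups
    ss_a = ss_total - ss_groups  # among groups

    df_a = n_groups - 1
    df_b = n_pops - n_groups
    df_c = int(n_total) - n_pops
    if df_a < 1 or df_b < 1 or df_c < 1:
        raise ValueError("degenerate design: need >=2 groups, more "
                         "populations than groups, and >1 sample per pop")

    group_sizes = np.array(
        [pop_sizes[group_of == g].sum() for g in range(n_groups)]
    )
    sum_np2_over_ng = sum(
        float(np.sum(pop_sizes[group_of == g] ** 2)) / group_sizes[g]
        for g in range(n_groups)
    )
    n_c = (n_total - sum_np2_over_ng) / df_b
    n_b = (sum_np2_over_ng - float(np.sum(pop_sizes**2)) / n_total) / df_a
    n_a = (n_total - float(np.sum(group_sizes**2)) / n_total) / df_a

    sigma_c = ss_wp / df_c
    sigma_b = (ss_b / df_b - sigma_c) / n_c
    sigma_a = (ss_a / df_a - sigma_c - n_b * sigma_b) / n_a
    return sigma_a, sigma_b, sigma_c


def _phi(sigma: tuple[float, float, float]) -> tuple[float, float, float]:
    a, b, c = sigma
    total = a + b + c
    phi_ct = a / total if total != 0 else 0.0
    phi_sc = b / (b + c) if (b + c) != 0 else 0.0
    phi_st = (a + b) / total if total != 0 else 0.0
    return phi_ct, phi_sc, phi_st


def _tabulate(
    records: Sequence[SampleRecord],
) -> tuple[list[str], list[str], np.ndarray, list[int]]:
    """Population list, class list, count matrix, per-individual class codes."""
    pops = sorted({r.population_code for r in records})
    classes = sorted({r.haplogroup for r in records if r.haplogroup})
    if any(r.haplogroup is None for r in records):
        raise ValueError("all records need an assigned haplogroup")
    counts = np.zeros((len(pops), len(classes)), dtype=int)
    codes = []
    for r in records:
        counts[pops.index(r.population_code), classes.index(r.haplogroup)] += 1
        codes.append(classes.index(r.haplogroup))
    return pops, classes, counts, codes


def amova(
    records: Sequence[SampleRecord],
    scheme: GroupingScheme,
    n_perm: int = 9999,
    seed: int = 0,
) -> AmovaResult:
    """Nested AMOVA of haplogroup identity under a population grouping.

    Permutation p-values use the convention p = (#{perm >= obs} + 1) /
    (n_perm + 1), with the scheme-appropriate unit permuted: whole
    populations across groups for Phi_CT, individuals across populations
    within their group for Phi_SC, individuals across all populations for
    Phi_ST.
    """
    pops, _, counts, _ = _tabulate(records)
    missing = [p for p in pops if p not in scheme.assignment]
    if missing:
        raise ValueError(f"populations not assigned to a group: {missing}")
    group_labels = sorted({scheme.assignment[p] for p in pops})
    if len(group_labels) < 2:
        raise ValueError("grouping scheme degenerates to a single group")
    group_of = np.array(
        [group_labels.index(scheme.assignment[p]) for p in pops]
    )
    n_groups = len(group_labels)
    pop_sizes = counts.sum(axis=1)
    if np.any(pop_sizes < 2):
        raise ValueError("each population needs >= 2 samples")

    if _ss_from_counts(counts.sum(axis=0)) == 0.0:
        return AmovaResult(
            sigma2=(0.0, 0.0, 0.0),
            pct_among_groups=0.0,
            pct_among_populations_within_groups=0.0,
            pct_within_populations=0.0,
            phi_ct=0.0, phi_sc=0.0, phi_st=0.0,
            p_values={"phi_ct": 1.0, "phi_sc": 1.0, "phi_st": 1.0},
            n_permutations=n_perm,
            no_variation=True,
            scheme=scheme.name,
            seed=seed,
        )

    sigma = _components(counts, group_of, n_groups)
    total = sum(sigma)
    phi_ct, phi_sc, phi_st = _phi(sigma)

    rng = np.random.default_rng(seed)
    n_classes = counts.shape[1]
    # per-individual (pop, class) arrays preserving the real structure
    ind_pop = np.concatenate(
        [np.full(pop_sizes[i], i) for i in range(len(pops))]
    )
    ind_class = np.concatenate(
        [np.repeat(np.arange(n_classes), counts[i]) for i in range(len(pops))]
    )

    def counts_from(ind_pop_v: np.ndarray, ind_class_v: np.ndarray) -> np.ndarray:
        c = np.zeros((len(pops), n_classes), dtype=int)
        np.add.at(c, (ind_pop_v, ind_class_v), 1)
        return c

    ge = {"phi_ct": 0, "phi_sc": 0, "phi_st": 0}
    for _ in range(n_perm):
        # Phi_ST: individuals across all populations
        perm = rng.permutation(ind_class)
        st = _phi(_components(counts_from(ind_pop, perm), group_of, n_groups))[2]
        if st >= phi_st - 1e-12:
            ge["phi_st"] += 1
        # Phi_SC: individuals across populations within their group
        perm_sc = ind_class.copy()
        for g in range(n_groups):
            mask = np.isin(ind_pop, np.where(group_of == g)[0])
            perm_sc[mask] = rng.permutation(perm_sc[mask])
        sc = _phi(_components(counts_from(ind_pop, perm_sc), group_of, n_groups))[1]
        if sc >= phi_sc - 1e-12:
            ge["phi_sc"] += 1
        # Phi_CT: whole populations across groups
        perm_groups = rng.permutation(group_of)
        try:
            ct = _phi(_components(counts, perm_groups, n_groups))[0]
        except ValueError:
            ct = np.inf  # unbalanced permutation left a group empty
        if ct >= phi_ct - 1e-12:
            ge["phi_ct"] += 1

    p_values = {k: (v + 1) / (n_perm + 1) for k, v in ge.items()}
    return AmovaResult(
        sigma2=sigma,
        pct_among_groups=100.0 * sigma[0] / total,
        pct_among_populations_within_groups=100.0 * sigma[1] / total,
        pct_within_populations=100.0 * sigma[2] / total,
        phi_ct=phi_ct, phi_sc=phi_sc, phi_st=phi_st,
        p_values=p_values,
        n_permutations=n_perm,
        scheme=scheme.name,
        seed=seed,
    )


def amova_oracle_ss(
    distances: np.ndarray,
    pop_of: Sequence[int],
    group_of_pop: Sequence[int],
) -> tuple[float, float, float]:
    """Brute-force sums of squares straight from a pairwise distance matrix.

    Independent check path: SS(S) = (1/|S|) sum_{i<j in S} d_ij^2 computed by
    explicit enumeration. Returns (SS among groups, SS among pops within
    groups, SS within pops).
    """
    pop_of = np.asarray(pop_of)
    group_of_pop = np.asarray(group_of_pop)
    group_of_ind = group_of_pop[pop_of]
    d2 = np.asarray(distances, dtype=float) ** 2
    n = d2.shape[0]

    def ss(idx: np.ndarray) -> float:
        if len(idx) == 0:
            return 0.0
        sub = d2[np.ix_(idx, idx)]
        return float(np.sum(np.triu(sub, k=1))) / len(idx)

    ss_total = ss(np.arange(n))
    ss_wp = sum(ss(np.where(pop_of == p)[0]) for p in np.unique(pop_of))
    ss_groups = sum(
        ss(np.where(group_of_ind == g)[0]) for g in np.unique(group_of_pop)
    )
    return ss_total - ss_groups, ss_groups - ss_wp, ss_wp


def mantel(
    dg: DistanceMatrix,
    dgeo: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Mantel matrix correlation with a two-sided permutation p-value.

    Permutation shuffles row/column labels of the second matrix jointly;
    p = (#{|r_perm| >= |r_obs|} + 1) / (n_perm + 1).
    """
    if dg.labels != dgeo.labels:
        raise ValueError("distance matrices must share labels and order")
    a, b = dg.d, dgeo.d
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("matrices must be finite")
    n = len(dg.labels)
    iu = np.triu_indices(n, k=1)
    x, y = a[iu], b[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a distance triangle")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = b[np.ix_(perm, perm)][iu]
        r_perm = float(np.corrcoef(x, yp)[0, 1])
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    return MantelResult(
        r=r_obs,
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
    )
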