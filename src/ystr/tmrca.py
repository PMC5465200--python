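"""Founder-based age estimation: the rho statistic and the ASD estimator.

rho is the mean number of mutational steps separating sampled haplotypes
from the founder; dividing by (loci x per-locus mutation rate) gives
generations, times the generation span gives years.  Its standard deviation
uses the branch formula sigma^2 = sum_b c_b^2 m_b / n^2 over a rooted
network when one is available (c_b lineages traverse branch b carrying m_b
mutations), falling back to the star-genealogy form sigma^2 = rho / n.

ASD averages squared per-locus allele differences from the founder; under
symmetric single-step mutation E[ASD] = mu * t, free of the homoplasy bias
that makes rho drift low at larger depths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from ystr.data_io import DYS19_INDEX, StrHaplotype
from ystr.str_clusters import step_distance

# imported lazily in functions to avoid an import cycle with mj_network


@dataclass(frozen=True)
class MutationModelParams:
    """Single-step mutation-model constants used for calibration."""

    mu: float = 2.1e-3  # mutations per locus per generation
    generation_years: float = 30.0
    n_loci: int = 15

    def __post_init__(self) -> None:
        # mu = 0 is allowed for null simulations; age conversion requires > 0
        if self.mu < 0 or self.generation_years <= 0 or self.n_loci < 1:
            raise ValueError("invalid mutation-model parameters")


DEFAULT_PARAMS = MutationModelParams()


@dataclass
class AgeEstimate:
    n: int
    rho: Optional[float] = None
    sigma_rho: Optional[float] = None
    age_rho_years: Optional[float] = None
    sd_rho_years: Optional[float] = None
    asd: Optional[float] = None
    age_asd_years: Optional[float] = None
    sigma_method: Optional[str] = None  # star | network


def _member_list(cluster) -> list[StrHaplotype]:
    members = getattr(cluster, "members", cluster)
    return list(members)


def _check_founder(haplotypes: Sequence[StrHaplotype], founder: StrHaplotype) -> None:
    for h in haplotypes:
        if len(h.alleles) != len(founder.alleles):
            raise ValueError("founder locus set does not match haplotypes")


def rho_age(
    cluster,
    founder: StrHaplotype,
    net=None,
    params: MutationModelParams = DEFAULT_PARAMS,
) -> AgeEstimate:
    """Rho-statistic age of a cluster relative to its founder haplotype.

    ``cluster`` is a haplotype list or a :class:`~ystr.mj_network.DescentCluster`.
    When a :class:`~ystr.mj_network.MedianNetwork` is supplied, sigma_rho
    follows the rooted-branch formula; otherwise a star genealogy is assumed.
    """
    haplotypes = _member_list(cluster)
    if not haplotypes:
        raise ValueError("empty cluster")
    if params.mu == 0:
        raise ValueError("age conversion requires mu > 0")
    _check_founder(haplotypes, founder)
    n = len(haplotypes)
    rho = sum(step_distance(h, founder) for h in haplotypes) / n
    generations = rho / (params.n_loci * params.mu)
    if net is not None:
        var = _branch_variance(net, founder, haplotypes)
        method = "network"
    else:
        var = rho / n
        method = "star"
    sigma_rho = math.sqrt(var)
    scale = 1.0 / (params.n_loci * params.mu) * params.generation_years
    return AgeEstimate(
        n=n,
        rho=rho,
        sigma_rho=sigma_rho,
        age_rho_years=generations * params.generation_years,
        sd_rho_years=sigma_rho * scale,
        sigma_method=method,
    )


def _branch_variance(net, founder: StrHaplotype, haplotypes) -> float:
    """sigma_rho^2 = (1/n^2) sum over branches of c_b^2 * m_b, where the
    branches are the founder-rooted shortest-path tree of the network."""
    from ystr.mj_network import _l1, _shortest_paths

    fnode = founder.alleles
    if fnode not in set(net.nodes):
        raise ValueError("founder profile absent from network")
    paths = _shortest_paths(net, fnode)
    usage: dict[tuple, int] = {}
    n = len(haplotypes)
    for h in haplotypes:
        if h.alleles not in paths:
            raise ValueError("cluster haplotype disconnected from founder")
        _, path = paths[h.alleles]
        for u, v in zip(path, path[1:]):
            key = (min(u, v), max(u, v))
            usage[key] = usage.get(key, 0) + 1
    var = sum(c * c * _l1(u, v) for (u, v), c in usage.items()) / (n * n)
    return var


def asd_age(
    cluster,
    founder: StrHaplotype,
    params: MutationModelParams = DEFAULT_PARAMS,
) -> AgeEstimate:
    """Average-squared-distance age relative to the founder.

    asd = (1/(n L)) sum_i sum_l (a_il - f_l)^2; generations = asd / mu.
    Haplotypes with a duplicated DYS19 have that locus excluded and their
    per-haplotype divisor reduced accordingly.
    """
    haplotypes = _member_list(cluster)
    if not haplotypes:
        raise ValueError("empty cluster")
    if params.mu == 0:
        raise ValueError("age conversion requires mu > 0")
    _check_founder(haplotypes, founder)
    n = len(haplotypes)
    per_locus_sum = 0.0
    for h in haplotypes:
        skip = h.dys19_duplicated or founder.dys19_duplicated
        sq = 0
        n_loci = 0
        for i, (a, f) in enumerate(zip(h.alleles, founder.alleles)):
            if skip and i == DYS19_INDEX:
                continue
            sq += (a - f) ** 2
            n_loci += 1
        per_locus_sum += sq / n_loci
    asd = per_locus_sum / n
    generations = asd / params.mu
    return AgeEstimate(
        n=n,
        asd=asd,
        age_asd_years=generations * params.generation_years,
    )


def date_cluster(
    cluster,
    founder: StrHaplotype,
    net=None,
    params: MutationModelParams = DEFAULT_PARAMS,
) -> AgeEstimate:
    """Combined rho + ASD estimate (convenience wrapper)."""
    r = rho_age(cluster, founder, net=net, params=params)
    a = asd_age(cluster, founder, params=params)
    return AgeEstimate(
        n=r.n,
        rho=r.rho,
        sigma_rho=r.sigma_rho,
        age_rho_years=r.age_rho_years,
        sd_rho_years=r.sd_rho_years,
        asd=a.asd,
        age_asd_years=a.age_asd_years,
        sigma_method=r.sigma_method,
    )
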