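"""Seeded simulation experiments used by the analysis drivers and checks.

The central experiment is ω-recovery: evolve a descendant from a random
ancestor coding sequence by an exact plan of synonymous and nonsynonymous
substitutions whose implied ω = (Nd/N)/(Sd/S) hits a target, then re-estimate
ω with NG86 counting and compare.  Because the generator applies at most one
hit per codon, the difference counts are recovered exactly and the only
estimator-side distortions are the Jukes–Cantor nonlinearity and the
ancestor/descendant averaging of site totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .divergence import AlignedCodingPair, kaks, ng86_sites
from .genetic_code import GeneticCode, vertebrate_mitochondrial
from .synthetic import SubstitutionPlan, evolve_cds, generate_cds


@dataclass(frozen=True)
class OmegaReplicate:
    replicate: int
    planted_omega: float
    estimated_omega: float
    sd_planted: int
    nd_planted: int
    sd_estimated: float
    nd_estimated: float


def ancestor_site_totals(cds: str, code: GeneticCode) -> tuple[float, float]:
    """NG86 (S, N) summed over the sense codons of one sequence."""
    S = N = 0.0
    for i in range(len(cds) // 3):
        codon = cds[3 * i : 3 * i + 3]
        if code.is_stop(codon):
            continue
        s, n = ng86_sites(codon, code)
        S += s
        N += n
    return S, N


def plan_for_omega(
    cds: str, omega: float, ps_target: float, code: GeneticCode
) -> tuple[SubstitutionPlan, float]:
    """Integer substitution plan whose implied ω is closest to the target.

    Returns the plan and its exact planted ω = (Nd/N)/(Sd/S) given the
    ancestor's site totals.
    """
    S, N = ancestor_site_totals(cds, code)
    sd = max(1, round(ps_target * S))
    nd = max(1, round(omega * N * sd / S))
    planted = (nd / N) / (sd / S)
    return SubstitutionPlan(n_synonymous=sd, n_nonsynonymous=nd), planted


def omega_recovery(
    omega: float,
    n_codons: int = 2000,
    n_replicates: int = 10,
    seed: int = 0,
    ps_target: float = 0.15,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Replicated planted-ω recovery under NG86 estimation.

    Each replicate draws a fresh ancestor of ``n_codons`` sense codons,
    evolves it in low-divergence mode (pS ≈ ``ps_target``), and estimates
    ω from the aligned pair.  Returns one row per replicate.
    """
    code = code or vertebrate_mitochondrial()
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        cds = generate_cds(n_codons, None, code, rng, ending="TAA")
        plan, planted = plan_for_omega(cds, omega, ps_target, code)
        descendant, _ = evolve_cds(cds, plan, code, rng)
        result = kaks(AlignedCodingPair(cds, descendant), code)
        rows.append(
            OmegaReplicate(
                replicate=rep,
                planted_omega=planted,
                estimated_omega=result.omega,
                sd_planted=plan.n_synonymous,
                nd_planted=plan.n_nonsynonymous,
                sd_estimated=result.Sd,
                nd_estimated=result.Nd,
            )
        )
    return pd.DataFrame(rows)
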