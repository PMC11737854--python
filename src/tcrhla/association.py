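"""Discovery of (clonotype, HLA allele) associations.

For every public clonotype and every allele, donors are cross-tabulated into
a 2x2 table (clonotype present/absent x allele positive/negative) and tested
with Fisher's two-tailed exact test; the Benjamini-Hochberg step-up
procedure controls the false discovery rate across all tests of a run
(default 1%).  Alpha-chain clonotypes are only tabulated over donors whose
alpha chain was sequenced, since absence is uninformative otherwise.

The two-sided p-value uses the point-probability rule: the sum of
hypergeometric probabilities of all tables with the observed margins whose
probability does not exceed that of the observed table.  It is computed in
exact integer arithmetic (binomial weights over a shared denominator), so
tie handling is exact and the value is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Dict, List, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import occurrence_matrix
from .types import Clonotype, Cohort, HlaAllele

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "fisher_two_tailed",
    "bh_adjust",
    "discover",
    "pairwise_tests",
    "write_associations",
    "read_associations",
]


@dataclass(frozen=True)
class AssociationRecord:
    """One (clonotype, allele) test: 2x2 counts, raw and BH-adjusted p,
    direction of the effect (enriched iff the sample odds ratio exceeds 1)."""

    clonotype: Clonotype
    allele: HlaAllele
    n_pp: int  # clonotype present, allele positive
    n_pn: int  # clonotype present, allele negative
    n_np: int  # clonotype absent, allele positive
    n_nn: int  # clonotype absent, allele negative
    p_raw: float
    p_adj: float

    @property
    def direction(self) -> str:
        return "enriched" if self.n_pp * self.n_nn > self.n_pn * self.n_np else "depleted"

    @property
    def n_carriers_total(self) -> int:
        return self.n_pp + self.n_pn

    @property
    def n_carriers_allele_positive(self) -> int:
        return self.n_pp


@lru_cache(maxsize=1_000_000)
def _fisher_exact_cached(n_pp: int, n_pn: int, n_np: int, n_nn: int) -> float:
    k = n_pp + n_pn          # clonotype carriers
    n_a = n_pp + n_np        # allele-positive donors
    n = n_pp + n_pn + n_np + n_nn
    lo = max(0, k + n_a - n)
    hi = min(k, n_a)
    w_obs = comb(k, n_pp) * comb(n - k, n_a - n_pp)
    num = 0
    den = 0
    for x in range(lo, hi + 1):
        w = comb(k, x) * comb(n - k, n_a - x)
        den += w
        if w <= w_obs:
            num += w
    return float(Fraction(num, den))


def fisher_two_tailed(n_pp: int, n_pn: int, n_np: int, n_nn: int) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 table (point-probability rule).

    Degenerate margins (an empty row or column) give p = 1.
    """
    if min(n_pp, n_pn, n_np, n_nn) < 0:
        raise ValueError("counts must be non-negative")
    if n_pp + n_pn + n_np + n_nn < 1:
        raise ValueError("table total must be >= 1")
    return _fisher_exact_cached(n_pp, n_pn, n_np, n_nn)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sort_key(r: AssociationRecord):
    return (
        r.p_adj,
        r.p_raw,
        r.allele.code,
        r.clonotype.chain,
        r.clonotype.v_family,
        r.clonotype.cdr3_aa,
    )


def pairwise_tests(
    cohort: Cohort,
    min_publicness: int = 3,
    min_allele_carriers: int = 5,
    alleles: Optional[Sequence[HlaAllele]] = None,
) -> List[AssociationRecord]:
    """Fisher-test every retained (public clonotype, allele) pair.

    Returns one record per tested pair with ``p_adj`` BH-adjusted over the
    full set of tests in this call.  Alleles carried by fewer than
    ``min_allele_carriers`` donors are skipped (logged).  For alpha-chain
    clonotypes only donors with alpha-chain data enter the table.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 donors")
    untyped = [d.donor_id for d in cohort if d.hla is None]
    if untyped:
        raise ValueError(f"all donors must be HLA-typed; untyped: {untyped[:5]}")

    clonotypes, presence = occurrence_matrix(cohort, min_publicness=min_publicness)
    if alleles is None:
        alleles = cohort.alleles()

    P = presence.to_numpy(dtype=bool)  # donors x clonotypes
    alpha_rows = np.array([d.has_alpha for d in cohort], dtype=bool)
    chain_is_alpha = np.array([c.chain == "alpha" for c in clonotypes], dtype=bool)

    records: List[AssociationRecord] = []
    for allele in alleles:
        carrier = np.array([d.has_allele(allele) for d in cohort], dtype=bool)
        n_carriers = int(carrier.sum())
        if n_carriers < min_allele_carriers:
            logger.info(
                "skipping allele %s: %d carriers < %d", allele.code, n_carriers, min_allele_carriers
            )
            continue
        for eligible, cols in (
            (np.ones(len(cohort), dtype=bool), ~chain_is_alpha),
            (alpha_rows, chain_is_alpha),
        ):
            idx = np.flatnonzero(cols)
            if idx.size == 0:
                continue
            sub_p = P[eligible][:, idx]
            sub_carrier = carrier[eligible]
            n_elig = int(eligible.sum())
            n_a = int(sub_carrier.sum())
            if n_a == 0 or n_elig < 2:
                continue
            n_pp_vec = sub_p[sub_carrier].sum(axis=0)
            n_tot_vec = sub_p.sum(axis=0)
            for j, col in enumerate(idx):
                n_pp = int(n_pp_vec[j])
                n_pn = int(n_tot_vec[j]) - n_pp
                n_np = n_a - n_pp
                n_nn = n_elig - n_pp - n_pn - n_np
                p = fisher_two_tailed(n_pp, n_pn, n_np, n_nn)
                records.append(
                    AssociationRecord(
                        clonotype=clonotypes[col],
                        allele=allele,
                        n_pp=n_pp,
                        n_pn=n_pn,
                        n_np=n_np,
                        n_nn=n_nn,
                        p_raw=p,
                        p_adj=p,  # placeholder, replaced below
                    )
                )
    if not records:
        return []
    adj = bh_adjust([r.p_raw for r in records])
    records = [
        AssociationRecord(
            clonotype=r.clonotype,
            allele=r.allele,
            n_pp=r.n_pp,
            n_pn=r.n_pn,
            n_np=r.n_np,
            n_nn=r.n_nn,
            p_raw=r.p_raw,
            p_adj=float(a),
        )
        for r, a in zip(records, adj)
    ]
    return records


def discover(
    cohort: Cohort,
    q: float = 0.01,
    min_publicness: int = 3,
    min_allele_carriers: int = 5,
    alleles: Optional[Sequence[HlaAllele]] = None,
) -> List[AssociationRecord]:
    """Significant (clonotype, allele) associations at BH FDR level ``q``.

    Tests every public clonotype against every allele, adjusts jointly, and
    returns records with ``p_adj <= q`` sorted by (p_adj, p_raw) with a
    deterministic tie-break.  Both enriched and depleted associations are
    returned; callers building classifiers typically keep the enriched ones.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    records = pairwise_tests(
        cohort,
        min_publicness=min_publicness,
        min_allele_carriers=min_allele_carriers,
        alleles=alleles,
    )
    hits = [r for r in records if r.p_adj <= q]
    return sorted(hits, key=_sort_key)


_ASSOC_COLUMNS = [
    "cdr3_aa",
    "v_family",
    "chain",
    "allele",
    "n_carriers_total",
    "n_carriers_allele_positive",
    "p_raw",
    "p_BH",
    "direction",
]


def write_associations(records: Sequence[AssociationRecord], path) -> None:
    """Write an association list as TSV (one row per (clonotype, allele))."""
    import pandas as pd

    rows = [
        {
            "cdr3_aa": r.clonotype.cdr3_aa,
            "v_family": r.clonotype.v_family,
            "chain": r.clonotype.chain,
            "allele": r.allele.code,
            "n_carriers_total": r.n_carriers_total,
            "n_carriers_allele_positive": r.n_carriers_allele_positive,
            "n_pp": r.n_pp,
            "n_pn": r.n_pn,
            "n_np": r.n_np,
            "n_nn": r.n_nn,
            "p_raw": r.p_raw,
            "p_BH": r.p_adj,
            "direction": r.direction,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ASSOC_COLUMNS + ["n_pp", "n_pn", "n_np", "n_nn"]).to_csv(
        path, sep="\t", index=False
    )


def read_associations(path) -> List[AssociationRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AssociationRecord(
                clonotype=Clonotype(chain=row.chain, cdr3_aa=row.cdr3_aa, v_family=row.v_family),
                allele=HlaAllele.parse(row.allele),
                n_pp=int(row.n_pp),
                n_pn=int(row.n_pn),
                n_np=int(row.n_np),
                n_nn=int(row.n_nn),
                p_raw=float(row.p_raw),
                p_adj=float(row.p_BH),
            )
        )
    return out
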