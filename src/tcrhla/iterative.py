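"""Semi-supervised iterative HLA typing of untyped cohorts.

Starting from a classifier trained on a typed cohort, untyped donors are
processed in random subgroups (default 100): each subgroup is typed with the
current model, appended to the working cohort with its imputed labels
frozen, associations are re-discovered on the augmented cohort, and the
classifier is refitted.  To contain error amplification and overfitting as
the cohort grows, the number of associations kept per iteration is budgeted
proportionally to the current donor count, the ratio being fixed at its
value in the initial cohort (budget replaces the fixed FDR threshold during
iteration; records are ranked by raw Fisher p).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .association import AssociationRecord, pairwise_tests
from .classifier import AlleleClassifier, features_for_allele, fit
from .types import Cohort, Donor, HlaAllele

logger = logging.getLogger(__name__)

__all__ = ["IterationRecord", "partition_untyped", "budgeted_discover", "iterate"]


@dataclass
class IterationRecord:
    iteration: int
    n_donors: int
    n_associations: int
    budget: int
    test_cross_entropy: float
    n_imputed_positive: int


def partition_untyped(
    cohort: Cohort, subgroup_size: int = 100, seed: int = 0
) -> List[List[Donor]]:
    """Random permutation, then consecutive chunks of ``subgroup_size``
    (final chunk may be smaller).  Deterministic in the seed."""
    if subgroup_size < 1:
        raise ValueError("subgroup_size must be >= 1")
    donors = list(cohort)
    if not donors:
        return []
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(donors))
    shuffled = [donors[i] for i in order]
    return [shuffled[i : i + subgroup_size] for i in range(0, len(shuffled), subgroup_size)]


def budgeted_discover(
    cohort: Cohort,
    allele: HlaAllele,
    budget: int,
    min_publicness: int = 3,
    min_allele_carriers: int = 5,
) -> List[AssociationRecord]:
    """Top-``budget`` association records for one allele, ranked by raw p.

    Runs the Fisher tests for this allele only and returns the ``budget``
    smallest raw p-values among tests with p < 1, with the deterministic
    tie-break of the association module.  No FDR threshold is applied — the
    donor-proportional budget replaces it.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    records = pairwise_tests(
        cohort,
        min_publicness=min_publicness,
        min_allele_carriers=min_allele_carriers,
        alleles=[allele],
    )
    informative = [r for r in records if r.p_raw < 1.0]
    informative.sort(
        key=lambda r: (
            r.p_raw,
            r.allele.code,
            r.clonotype.chain,
            r.clonotype.v_family,
            r.clonotype.cdr3_aa,
        )
    )
    return informative[:budget]


def _with_imputed_label(donor: Donor, allele: HlaAllele, positive: bool) -> Donor:
    hla = frozenset([allele]) if positive else frozenset()
    return Donor(
        donor_id=donor.donor_id,
        cohort=donor.cohort,
        clonotypes=donor.clonotypes,
        has_alpha=donor.has_alpha,
        hla=hla,
    )


def iterate(
    initial: Cohort,
    untyped: Cohort,
    allele: HlaAllele,
    subgroup_size: int = 100,
    seed: int = 0,
    penalty: str = "l1",
    matching: str = "exact",
    min_publicness: int = 3,
    min_allele_carriers: int = 5,
    initial_associations: Optional[Sequence[AssociationRecord]] = None,
    q: float = 0.01,
) -> Tuple[AlleleClassifier, List[IterationRecord], pd.DataFrame]:
    """Run the typing recursion for one allele.

    Returns the final model, the per-iteration history, and the table of
    imputed per-donor calls (frozen once assigned, never revised).

    The association budget ratio is fixed at iteration 0:
    ``n_initial_associations / n_initial_donors``; at each iteration the
    budget is ``ceil(ratio * current_donor_count)``.
    """
    from .association import discover  # local import to avoid cycle noise

    if initial_associations is None:
        initial_associations = discover(
            initial,
            q=q,
            min_publicness=min_publicness,
            min_allele_carriers=min_allele_carriers,
            alleles=[allele],
        )
    init_records = [r for r in initial_associations if r.allele == allele]
    if not init_records:
        raise ValueError(f"no initial associations for {allele.code}; cannot start recursion")
    budget_ratio = len(init_records) / len(initial)

    model = fit(
        initial,
        allele,
        associations=init_records,
        penalty=penalty,
        matching=matching,
        split_seed=seed,
    )
    history: List[IterationRecord] = []
    imputed_rows: List[dict] = []
    working = Cohort(donors=list(initial), name=initial.name)
    subgroups = partition_untyped(untyped, subgroup_size=subgroup_size, seed=seed)

    for t, subgroup in enumerate(subgroups, start=1):
        # (1) type the next subgroup with the current model
        labelled = []
        n_pos = 0
        for d in subgroup:
            p = model.predict_donor(d)
            positive = p >= model.threshold
            n_pos += int(positive)
            imputed_rows.append(
                {
                    "iteration": t,
                    "donor_id": d.donor_id,
                    "allele": allele.code,
                    "probability": p,
                    "call": int(positive),
                }
            )
            labelled.append(_with_imputed_label(d, allele, positive))
        # (2) freeze the imputed labels into the working cohort
        working = Cohort(donors=list(working) + labelled, name=working.name)
        # (3) re-discover under the donor-proportional budget
        budget = math.ceil(budget_ratio * len(working))
        try:
            records = budgeted_discover(
                working,
                allele,
                budget=budget,
                min_publicness=min_publicness,
                min_allele_carriers=min_allele_carriers,
            )
            feats = features_for_allele(records, allele, enriched_only=True)
            if not feats:
                raise ValueError("budgeted discovery produced no enriched features")
            # (4) refit on the augmented cohort with a fresh 70/30 split
            model = fit(
                working,
                allele,
                features=feats,
                penalty=penalty,
                matching=matching,
                split_seed=seed + t,
            )
        except ValueError as exc:
            logger.warning("iteration %d aborted: %s", t, exc)
            break
        history.append(
            IterationRecord(
                iteration=t,
                n_donors=len(working),
                n_associations=len(records),
                budget=budget,
                test_cross_entropy=model.meta["test_cross_entropy"],
                n_imputed_positive=n_pos,
            )
        )

    imputed = pd.DataFrame(
        imputed_rows, columns=["iteration", "donor_id", "allele", "probability", "call"]
    )
    return model, history, imputed


def history_to_frame(history: Sequence[IterationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "iteration": h.iteration,
                "n_donors": h.n_donors,
                "n_associations": h.n_associations,
                "budget": h.budget,
                "test_cross_entropy": h.test_cross_entropy,
                "n_imputed_positive": h.n_imputed_positive,
            }
            for h in history
        ]
    )
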