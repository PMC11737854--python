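"""Per-allele logistic classifiers on presence/absence of associated TCRs.

For allele *a* the probability that a donor is positive is modelled as

    p_a = 1 / (1 + exp(-sum_i w_ai x_i - v_a y - b_a))

where x_i indicates presence of the i-th allele-associated clonotype in the
donor's repertoire, y indicates whether the donor's alpha chain was
sequenced (v_a soaks up the systematic shift in alpha-feature availability),
and b_a is an optional intercept.  Weights are fitted by penalized maximum
likelihood (L1 by default, which drives most weights to exactly zero); the
penalty strength is chosen on a geometric grid by cross-entropy on a
held-out 30% split.

Feature presence can be *exact* (identical clonotype triple) or *fuzzy*:
a feature counts as present when the donor has a clonotype of the same
chain, V family and CDR3 length within Hamming distance 1 of the feature's
CDR3.  A weight-free variant simply counts matches; ranking donors by match
count is equivalent to ranking by the unit-weight logistic score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split

from .association import AssociationRecord
from .types import Clonotype, Cohort, Donor, HlaAllele

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "AlleleClassifier",
    "encode",
    "encode_cohort",
    "features_for_allele",
    "fit",
    "count_classifier",
    "predict_cohort",
    "DEFAULT_C_GRID",
]

#: Geometric grid of inverse regularization strengths (sklearn's C), 20
#: points spanning 1e-3 .. 1e3.
DEFAULT_C_GRID: Tuple[float, ...] = tuple(np.geomspace(1e-3, 1e3, 20))


@dataclass
class FeatureVector:
    """Binary presence vector over an allele's associated clonotypes, plus
    the alpha-sequenced indicator y."""

    x: np.ndarray
    y: int


def _fuzzy_hit(cdr3: str, candidates: Sequence[str]) -> bool:
    for other in candidates:
        mism = 0
        for a, b in zip(cdr3, other):
            if a != b:
                mism += 1
                if mism > 1:
                    break
        if mism <= 1:
            return True
    return False


def encode(donor: Donor, features: Sequence[Clonotype], matching: str = "exact") -> FeatureVector:
    """Encode one donor against a feature list.

    ``matching='exact'``: x_i = 1 iff the exact (chain, cdr3, V family)
    triple is in the repertoire.  ``matching='fuzzy1'``: same chain, same V
    family, same CDR3 length, Hamming distance <= 1.  Alpha features are
    structurally 0 for donors without alpha-chain data.
    """
    if matching not in ("exact", "fuzzy1"):
        raise ValueError(f"unknown matching mode {matching!r}")
    if len(features) == 0:
        raise ValueError("feature list must be non-empty")
    y = int(bool(donor.has_alpha))
    x = np.zeros(len(features), dtype=np.int8)
    if matching == "exact":
        repertoire = donor.clonotypes
        for i, f in enumerate(features):
            if f in repertoire:
                x[i] = 1
    else:
        buckets: Dict[Tuple[str, str, int], List[str]] = {}
        for c in donor.clonotypes:
            buckets.setdefault((c.chain, c.v_family, len(c.cdr3_aa)), []).append(c.cdr3_aa)
        for i, f in enumerate(features):
            cands = buckets.get((f.chain, f.v_family, len(f.cdr3_aa)))
            if cands and _fuzzy_hit(f.cdr3_aa, cands):
                x[i] = 1
    if y == 0:
        for i, f in enumerate(features):
            if f.chain == "alpha":
                x[i] = 0
    return FeatureVector(x=x, y=y)


def encode_cohort(
    cohort: Cohort, features: Sequence[Clonotype], matching: str = "exact"
) -> Tuple[np.ndarray, np.ndarray]:
    """Stacked design matrix (n_donors x n_features) and y indicator vector."""
    fvs = [encode(d, features, matching) for d in cohort]
    X = np.stack([fv.x for fv in fvs]).astype(float)
    y = np.array([fv.y for fv in fvs], dtype=float)
    return X, y


def features_for_allele(
    associations: Sequence[AssociationRecord],
    allele: HlaAllele,
    enriched_only: bool = True,
) -> List[Clonotype]:
    """Deterministically ordered feature clonotypes for one allele."""
    feats = {
        r.clonotype
        for r in associations
        if r.allele == allele and (r.direction == "enriched" or not enriched_only)
    }
    return sorted(feats, key=lambda c: (c.chain, c.v_family, c.cdr3_aa))


@dataclass
class AlleleClassifier:
    """A fitted per-allele logistic model (weights over feature clonotypes,
    alpha-indicator weight v, intercept b, decision threshold)."""

    allele: HlaAllele
    features: List[Clonotype]
    w: np.ndarray
    v: float
    b: float
    threshold: float = 0.5
    penalty: str = "l1"
    C: float = 1.0
    matching: str = "exact"
    meta: dict = field(default_factory=dict)

    def linear_score(self, fv: FeatureVector) -> float:
        if fv.x.shape[0] != len(self.features):
            raise ValueError(
                f"feature vector length {fv.x.shape[0]} != model features {len(self.features)}"
            )
        return float(np.dot(self.w, fv.x) + self.v * fv.y + self.b)

    def predict_proba(self, fv: FeatureVector) -> float:
        """Logistic probability that the donor carries the allele; in (0,1)."""
        z = self.linear_score(fv)
        if z >= 0:
            return 1.0 / (1.0 + np.exp(-z))
        e = np.exp(z)
        return float(e / (1.0 + e))

    def predict_donor(self, donor: Donor) -> float:
        return self.predict_proba(encode(donor, self.features, self.matching))

    @property
    def sparsity(self) -> float:
        """Fraction of exactly-zero feature weights."""
        return float(np.mean(self.w == 0.0))

    def to_json(self) -> str:
        doc = {
            "allele": self.allele.code,
            "features": [[c.chain, c.cdr3_aa, c.v_family] for c in self.features],
            "w": list(map(float, self.w)),
            "v": self.v,
            "b": self.b,
            "threshold": self.threshold,
            "penalty": self.penalty,
            "C": self.C,
            "matching": self.matching,
            "meta": self.meta,
        }
        return json.dumps(doc, indent=1)

    @staticmethod
    def from_json(text: str) -> "AlleleClassifier":
        doc = json.loads(text)
        return AlleleClassifier(
            allele=HlaAllele.parse(doc["allele"]),
            features=[Clonotype(chain=c, cdr3_aa=s, v_family=v) for c, s, v in doc["features"]],
            w=np.array(doc["w"], dtype=float),
            v=float(doc["v"]),
            b=float(doc["b"]),
            threshold=float(doc["threshold"]),
            penalty=doc["penalty"],
            C=float(doc["C"]),
            matching=doc["matching"],
            meta=doc.get("meta", {}),
        )


def _penalty_kwargs(penalty: str) -> dict:
    # sklearn >= 1.8 expresses the penalty through l1_ratio and deprecates
    # the `penalty` argument; keep both spellings working.
    import sklearn

    version = tuple(int(x) for x in sklearn.__version__.split(".")[:2])
    if version >= (1, 8):
        return {"l1_ratio": 1.0 if penalty == "l1" else 0.0}
    return {"penalty": penalty}


def _fit_one(
    X: np.ndarray, labels: np.ndarray, penalty: str, C: float, fit_intercept: bool
) -> LogisticRegression:
    model = LogisticRegression(
        C=C,
        solver="liblinear",
        fit_intercept=fit_intercept,
        max_iter=2000,
        tol=1e-8,
        random_state=0,
        **_penalty_kwargs(penalty),
    )
    model.fit(X, labels)
    return model


def fit(
    train: Cohort,
    allele: HlaAllele,
    associations: Optional[Sequence[AssociationRecord]] = None,
    features: Optional[Sequence[Clonotype]] = None,
    penalty: str = "l1",
    matching: str = "exact",
    split_seed: int = 0,
    test_fraction: float = 0.3,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    fit_intercept: bool = True,
    enriched_only: bool = True,
) -> AlleleClassifier:
    """Fit a per-allele classifier with held-out selection of the penalty.

    Donors are split 70/30 (stratified by allele status so both portions
    contain positives); for every grid strength a penalized logistic model
    is fitted on the 70% and scored by cross-entropy on the 30%; the
    strength with the smallest held-out loss wins, ties going to the
    stronger penalty (smaller C, sparser model).  The final reported model
    is the winning grid fit.

    Features are taken from ``features`` if given, else from the enriched
    associations of ``allele`` in ``associations``.
    """
    if penalty not in ("l1", "l2"):
        raise ValueError(f"penalty must be 'l1' or 'l2', got {penalty!r}")
    if features is None:
        if associations is None:
            raise ValueError("provide either `associations` or an explicit `features` list")
        features = features_for_allele(associations, allele, enriched_only=enriched_only)
    features = list(features)
    if not features:
        raise ValueError(f"no features: allele {allele.code} has no associated clonotypes")

    labels = np.array([d.has_allele(allele) for d in train], dtype=int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError(f"need both positive and negative donors for {allele.code}")

    X, y_ind = encode_cohort(train, features, matching)
    design = np.column_stack([X, y_ind])  # alpha indicator as the last column

    idx = np.arange(len(labels))
    idx_train, idx_test = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=split_seed,
        stratify=labels,
    )

    best = None
    grid_report = []  # (C, held-out loss, nonzero feature weights)
    for C in sorted(c_grid):  # ascending C = descending penalty strength
        model = _fit_one(design[idx_train], labels[idx_train], penalty, C, fit_intercept)
        proba = model.predict_proba(design[idx_test])[:, 1]
        loss = log_loss(labels[idx_test], proba, labels=[0, 1])
        grid_report.append((float(C), float(loss), int(np.sum(model.coef_.ravel()[:-1] != 0.0))))
        # strict improvement required, so ties keep the stronger penalty
        if best is None or loss < best[0] - 1e-12:
            best = (loss, C, model)
    loss, C, model = best

    coef = model.coef_.ravel()
    clf = AlleleClassifier(
        allele=allele,
        features=features,
        w=coef[:-1].copy(),
        v=float(coef[-1]),
        b=float(model.intercept_[0]) if fit_intercept else 0.0,
        threshold=0.5,
        penalty=penalty,
        C=float(C),
        matching=matching,
        meta={
            "split_seed": split_seed,
            "test_fraction": test_fraction,
            "c_grid": list(map(float, c_grid)),
            "grid_report": grid_report,
            "test_cross_entropy": float(loss),
            "n_train": int(len(idx_train)),
            "n_test": int(len(idx_test)),
            "n_positive": int(labels.sum()),
        },
    )
    return clf


def count_classifier(
    donor: Donor,
    features: Sequence[Clonotype],
    matching: str = "exact",
    threshold: int = 1,
) -> Tuple[int, bool]:
    """Weight-free variant: the number of feature matches in the repertoire
    and the call (count >= threshold).  Ranking donors by this count equals
    ranking by the unit-weight logistic score, since the logistic function
    is strictly increasing in the linear score."""
    fv = encode(donor, features, matching)
    count = int(fv.x.sum())
    return count, count >= threshold


def predict_cohort(models: Sequence[AlleleClassifier], cohort: Cohort) -> pd.DataFrame:
    """Long-form predictions: one row per (donor, allele) with the logistic
    probability and the thresholded binary call."""
    if not models:
        raise ValueError("no models supplied")
    rows = []
    for donor in cohort:
        for m in models:
            p = m.predict_donor(donor)
            rows.append(
                {
                    "donor_id": donor.donor_id,
                    "allele": m.allele.code,
                    "probability": p,
                    "call": int(p >= m.threshold),
                }
            )
    return pd.DataFrame(rows, columns=["donor_id", "allele", "probability", "call"])
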