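"""Synthetic HLA-typed repertoire cohorts with planted TCR-HLA associations.

The generator emulates the statistical skeleton of a cohort of HLA-typed
donors sharing public clonotypes:

* each donor's alleles are drawn independently per allele at its configured
  population frequency, subject to at most two alleles per class-I locus;
* *background* clonotypes are present in each donor i.i.d. with a common
  sharing probability — they carry no HLA signal and provide the null for
  FDR calibration;
* *planted* clonotypes are present with probability ``p_present_given_positive``
  in carriers of their target allele and ``p_present_given_negative``
  otherwise;
* alpha-chain clonotypes are only generated for donors flagged as having
  alpha-chain sequencing data.

Synthetic CDR3s are random strings over the 20 amino acids, length 8-20,
starting with 'C' and ending with 'F', so that length- and mismatch-based
machinery downstream is exercised realistically.  Everything is reproducible
from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .types import CLASS_I_LOCI, Clonotype, Cohort, Donor, HlaAllele

__all__ = [
    "PlantedAssociation",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_untyped",
    "split_cohort",
    "strip_typing",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_V_FAMILIES = {
    "beta": [f"TRBV{i}" for i in range(2, 31)],
    "alpha": [f"TRAV{i}" for i in range(1, 42)],
}


@dataclass(frozen=True)
class PlantedAssociation:
    """One planted allele signal: ``n_clonotypes`` clonotypes enriched in
    carriers of ``allele`` (``p_pos`` >= ``p_neg``; equal means null)."""

    allele: HlaAllele
    n_clonotypes: int
    p_pos: float
    p_neg: float
    chain: str = "beta"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_neg <= self.p_pos <= 1.0):
            raise ValueError(
                f"planted association for {self.allele.code}: need 0 <= p_neg <= p_pos <= 1"
            )

    @property
    def is_null(self) -> bool:
        return self.p_pos == self.p_neg


@dataclass
class SimulationConfig:
    n_donors: int
    allele_panel: Sequence[Tuple[HlaAllele, float]]
    n_background_clonotypes: int = 500
    background_sharing: float = 0.1
    planted_associations: Sequence[PlantedAssociation] = field(default_factory=tuple)
    alpha_fraction: float = 1.0
    background_alpha_fraction: float = 0.0  # fraction of background clonotypes on the alpha chain
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        for allele, freq in self.allele_panel:
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"allele frequency for {allele.code} outside [0,1]")
        if not 0.0 <= self.background_sharing <= 1.0:
            raise ValueError("background_sharing outside [0,1]")
        if not 0.0 <= self.alpha_fraction <= 1.0:
            raise ValueError("alpha_fraction outside [0,1]")
        for locus in CLASS_I_LOCI:
            forced = sum(
                1 for a, f in self.allele_panel if a.locus == locus and f == 1.0
            )
            if forced > 2:
                raise ValueError(
                    f"infeasible panel: {forced} alleles forced (frequency 1.0) at class-I locus {locus}"
                )
        panel_alleles = {a for a, _ in self.allele_panel}
        for p in self.planted_associations:
            if p.allele not in panel_alleles:
                raise ValueError(f"planted allele {p.allele.code} not in allele_panel")


def _random_cdr3s(rng: np.random.Generator, n: int, taken: Set[str]) -> List[str]:
    """Distinct random CDR3s: length 8-20, C...F, standard alphabet."""
    out: List[str] = []
    while len(out) < n:
        length = int(rng.integers(8, 21))
        middle = "".join(rng.choice(_AA, size=length - 2))
        s = "C" + middle + "F"
        if s not in taken:
            taken.add(s)
            out.append(s)
    return out


def _make_clonotypes(
    rng: np.random.Generator, n: int, chain: str, taken: Set[str]
) -> List[Clonotype]:
    cdr3s = _random_cdr3s(rng, n, taken)
    fams = rng.choice(_V_FAMILIES[chain], size=n)
    return [Clonotype(chain=chain, cdr3_aa=s, v_family=str(f)) for s, f in zip(cdr3s, fams)]


def _draw_hla(
    rng: np.random.Generator, panel: Sequence[Tuple[HlaAllele, float]]
) -> frozenset:
    """Independent Bernoulli draw per allele; if a class-I locus exceeds two
    positives, randomly drop non-forced positives until the constraint holds."""
    positives = [a for a, f in panel if rng.random() < f]
    freq = dict(panel)
    for locus in CLASS_I_LOCI:
        at_locus = [a for a in positives if a.locus == locus]
        while len(at_locus) > 2:
            droppable = [a for a in at_locus if freq[a] < 1.0]
            victim = droppable[int(rng.integers(len(droppable)))]
            positives.remove(victim)
            at_locus.remove(victim)
    return frozenset(positives)


def simulate_cohort(
    config: SimulationConfig, name: str = "sim"
) -> Tuple[Cohort, pd.DataFrame]:
    """Simulate a typed cohort; returns (cohort, truth table).

    The truth table has one row per planted clonotype with columns
    ``chain, cdr3_aa, v_family, allele, p_pos, p_neg, is_null``.  Identical
    config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    taken: Set[str] = set()
    n_bg_alpha = int(round(config.n_background_clonotypes * config.background_alpha_fraction))
    n_bg_beta = config.n_background_clonotypes - n_bg_alpha
    background = _make_clonotypes(rng, n_bg_beta, "beta", taken) + _make_clonotypes(
        rng, n_bg_alpha, "alpha", taken
    )
    planted: List[Tuple[Clonotype, PlantedAssociation]] = []
    for p in config.planted_associations:
        for c in _make_clonotypes(rng, p.n_clonotypes, p.chain, taken):
            planted.append((c, p))

    donors: List[Donor] = []
    ndig = max(3, len(str(config.n_donors)))
    for i in range(config.n_donors):
        hla = _draw_hla(rng, config.allele_panel)
        has_alpha = bool(rng.random() < config.alpha_fraction)
        clonos: List[Clonotype] = []
        present = rng.random(len(background)) < config.background_sharing
        for c, keep in zip(background, present):
            if keep and (has_alpha or c.chain == "beta"):
                clonos.append(c)
        for c, p in planted:
            prob = p.p_pos if p.allele in hla else p.p_neg
            if rng.random() < prob and (has_alpha or c.chain == "beta"):
                clonos.append(c)
        donors.append(
            Donor(
                donor_id=f"{name}{i:0{ndig}d}",
                cohort=name,
                clonotypes=frozenset(clonos),
                has_alpha=has_alpha,
                hla=hla,
            )
        )

    truth = pd.DataFrame(
        [
            {
                "chain": c.chain,
                "cdr3_aa": c.cdr3_aa,
                "v_family": c.v_family,
                "allele": p.allele.code,
                "p_pos": p.p_pos,
                "p_neg": p.p_neg,
                "is_null": p.is_null,
            }
            for c, p in planted
        ],
        columns=["chain", "cdr3_aa", "v_family", "allele", "p_pos", "p_neg", "is_null"],
    )
    return Cohort(donors=donors, name=name), truth


def split_cohort(
    cohort: Cohort, sizes: Sequence[int], seed: int = 0
) -> List[Cohort]:
    """Randomly partition a cohort into disjoint sub-cohorts of given sizes.

    Donors in every part come from the same simulation, so they share one
    clonotype universe — required when one part trains a classifier that is
    applied to another.  ``sum(sizes)`` may be smaller than the cohort;
    leftovers are discarded.  Deterministic in the seed.
    """
    if sum(sizes) > len(cohort):
        raise ValueError(f"requested {sum(sizes)} donors from a cohort of {len(cohort)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    donors = [cohort.donors[i] for i in order]
    parts: List[Cohort] = []
    start = 0
    for i, n in enumerate(sizes):
        parts.append(Cohort(donors=donors[start : start + n], name=f"{cohort.name}_part{i}"))
        start += n
    return parts


def strip_typing(cohort: Cohort) -> Tuple[Cohort, Dict[str, frozenset]]:
    """Remove HLA typings from a cohort, returning the stripped cohort and
    the hidden truth (donor_id -> allele set) for evaluation only."""
    hidden = {d.donor_id: d.hla for d in cohort}
    stripped = [
        Donor(
            donor_id=d.donor_id,
            cohort=d.cohort,
            clonotypes=d.clonotypes,
            has_alpha=d.has_alpha,
            hla=None,
        )
        for d in cohort
    ]
    return Cohort(donors=stripped, name=cohort.name), hidden


def simulate_untyped(
    config: SimulationConfig, name: str = "sim"
) -> Tuple[Cohort, Dict[str, frozenset], pd.DataFrame]:
    """As :func:`simulate_cohort`, but the returned cohort carries no HLA
    typing; the hidden truth is returned separately for evaluation only."""
    cohort, truth = simulate_cohort(config, name=name)
    hidden = {d.donor_id: d.hla for d in cohort}
    stripped = [
        Donor(
            donor_id=d.donor_id,
            cohort=d.cohort,
            clonotypes=d.clonotypes,
            has_alpha=d.has_alpha,
            hla=None,
        )
        for d in cohort
    ]
    return Cohort(donors=stripped, name=name), hidden, truth
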