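"""Core domain types for TCR-repertoire / HLA analysis.

A *clonotype* is a chain-tagged amino-acid CDR3 plus a V-gene family — the
unit of publicness and of association testing.  An *HLA allele* is a locus
plus a 4-digit-resolution code (e.g. ``A*02:01``).  A *donor* is a repertoire
(a set of clonotypes) with optional HLA typing; a *cohort* is a list of
donors with unique ids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "AA_ALPHABET",
    "CLASS_I_LOCI",
    "CLASS_II_LOCI",
    "Clonotype",
    "HlaAllele",
    "Donor",
    "Cohort",
]

#: The 20 standard amino acids.  CDR3s containing anything else (stop '*',
#: frameshift '_', lowercase) are non-productive and filtered on read.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DPA1", "DPB1", "DQA1", "DQB1", "DRB1", "DRB3", "DRB4", "DRB5")
_KNOWN_LOCI = CLASS_I_LOCI + CLASS_II_LOCI

_ALLELE_RE = re.compile(r"^([A-Z0-9]+)\*(\d{2,})(?::(\d{2,}))?((?::\d{2,})*)[A-Z]?$")


@dataclass(frozen=True, order=True)
class Clonotype:
    """A TCR clonotype: (chain, CDR3 amino-acid sequence, V-gene family).

    Identity (equality / hashing) is exactly this triple.
    """

    chain: str  # "alpha" | "beta"
    cdr3_aa: str
    v_family: str

    def __post_init__(self) -> None:
        if self.chain not in ("alpha", "beta"):
            raise ValueError(f"chain must be 'alpha' or 'beta', got {self.chain!r}")
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"cdr3_aa {self.cdr3_aa!r} contains non-standard characters {sorted(bad)}"
            )
        expected = "TRAV" if self.chain == "alpha" else "TRBV"
        if not self.v_family.startswith(expected):
            raise ValueError(
                f"{self.chain} clonotype must use a {expected} family, got {self.v_family!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chain}:{self.v_family}:{self.cdr3_aa}"


@dataclass(frozen=True, order=True)
class HlaAllele:
    """An HLA allele at 4-digit (protein-level) resolution, e.g. ``A*02:01``."""

    locus: str
    code: str

    @staticmethod
    def parse(token: str) -> "HlaAllele":
        """Parse and normalize an allele code to 4-digit resolution.

        Codes with more than 4-digit resolution (``A*02:01:01``) are
        truncated; 2-digit allele groups (``A*02``) are rejected because the
        protein-level field is required.
        """
        token = token.strip()
        m = _ALLELE_RE.match(token)
        if not m:
            raise ValueError(f"unparseable HLA allele code: {token!r}")
        locus, group, protein = m.group(1), m.group(2), m.group(3)
        if locus not in _KNOWN_LOCI:
            raise ValueError(f"unknown HLA locus {locus!r} in {token!r}")
        if protein is None:
            raise ValueError(
                f"allele {token!r} is at 2-digit resolution; 4-digit resolution required"
            )
        return HlaAllele(locus=locus, code=f"{locus}*{group}:{protein}")

    def __post_init__(self) -> None:
        if self.locus not in _KNOWN_LOCI:
            raise ValueError(f"unknown HLA locus {self.locus!r}")
        if not self.code.startswith(self.locus + "*"):
            raise ValueError(f"code {self.code!r} does not match locus {self.locus!r}")

    @property
    def mhc_class(self) -> str:
        """'I' for loci A/B/C, 'II' for the DP/DQ/DR loci."""
        return "I" if self.locus in CLASS_I_LOCI else "II"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


@dataclass
class Donor:
    """One donor: a clonotype set, an alpha-availability flag, optional typing.

    ``has_alpha`` records whether the alpha chain was sequenced for this
    donor.  An explicit flag passed by the caller wins over inference from
    content, because alpha sequencing may simply have yielded no retained
    clonotypes.
    """

    donor_id: str
    cohort: str = ""
    clonotypes: frozenset = field(default_factory=frozenset)
    has_alpha: Optional[bool] = None
    hla: Optional[frozenset] = None

    def __post_init__(self) -> None:
        self.clonotypes = frozenset(self.clonotypes)
        if self.has_alpha is None:
            self.has_alpha = any(c.chain == "alpha" for c in self.clonotypes)
        if self.hla is not None:
            self.hla = frozenset(self.hla)
            for locus in CLASS_I_LOCI:
                n = sum(1 for a in self.hla if a.locus == locus)
                if n > 2:
                    raise ValueError(
                        f"donor {self.donor_id}: {n} alleles at class-I locus {locus} (max 2)"
                    )

    def clonotypes_of_chain(self, chain: str) -> frozenset:
        return frozenset(c for c in self.clonotypes if c.chain == chain)

    def has_allele(self, allele: HlaAllele) -> bool:
        return self.hla is not None and allele in self.hla


@dataclass
class Cohort:
    """A named list of donors with unique donor ids."""

    donors: list
    name: str = "cohort"

    def __post_init__(self) -> None:
        ids = [d.donor_id for d in self.donors]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate donor ids in cohort {self.name!r}: {sorted(dups)}")

    def __len__(self) -> int:
        return len(self.donors)

    def __iter__(self):
        return iter(self.donors)

    def alleles(self) -> list:
        """Sorted distinct alleles carried by any typed donor."""
        out = set()
        for d in self.donors:
            if d.hla:
                out |= d.hla
        return sorted(out)

    def subset(self, donor_ids: Iterable[str], name: Optional[str] = None) -> "Cohort":
        wanted = set(donor_ids)
        return Cohort(
            donors=[d for d in self.donors if d.donor_id in wanted],
            name=name or self.name,
        )
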