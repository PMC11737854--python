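"""Reading and writing clonotype tables, HLA typings and occurrence matrices.

Two clonotype table formats are supported, both tab-separated with a header:

* ``airr`` — AIRR Rearrangement columns ``junction_aa``, ``v_call`` and
  ``locus`` (TRA/TRB); only the columns needed here are consumed.
* ``simple`` — columns ``chain`` (alpha/beta), ``cdr3_aa``, ``v_family``.

On read, non-productive CDR3s (stop ``*``, frameshift ``_``, lowercase, or
any character outside the 20 standard amino acids) are dropped and V calls
are truncated to family level (``TRBV19-01*01`` -> ``TRBV19``), so that
clonotype identity and sharing counts are well defined across datasets.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .types import AA_ALPHABET, CLASS_I_LOCI, Clonotype, Cohort, Donor, HlaAllele

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_v_family",
    "read_clonotype_table",
    "write_clonotype_table",
    "read_hla_table",
    "write_hla_table",
    "assemble_cohort",
    "occurrence_matrix",
]

_AIRR_COLUMNS = ("junction_aa", "v_call", "locus")
_SIMPLE_COLUMNS = ("chain", "cdr3_aa", "v_family")
_LOCUS_TO_CHAIN = {"TRA": "alpha", "TRB": "beta"}


def normalize_v_family(v_call: str) -> str:
    """Truncate a V call to family level: strip the allele (``*xx``) and
    gene (``-k``) suffixes, e.g. ``TRBV19-01*01`` -> ``TRBV19``.

    Idempotent: an already-normalized family is returned unchanged.
    """
    return v_call.strip().split("*")[0].split("-")[0]


def _productive(cdr3: str) -> bool:
    return bool(cdr3) and set(cdr3) <= AA_ALPHABET


def read_clonotype_table(
    path,
    format: str = "simple",
    donor_id: str = "donor",
    cohort: str = "",
    has_alpha: Optional[bool] = None,
) -> Donor:
    """Read one donor's clonotype table into a deduplicated, filtered Donor.

    Parameters
    ----------
    format
        ``"airr"`` or ``"simple"`` (see module docstring).
    has_alpha
        Explicit alpha-sequencing flag; if ``None`` it is inferred from the
        presence of alpha-chain clonotypes after filtering.
    """
    if format not in ("airr", "simple"):
        raise ValueError(f"unknown clonotype table format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = _AIRR_COLUMNS if format == "airr" else _SIMPLE_COLUMNS
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r} for format {format!r}")

    clonotypes: Set[Clonotype] = set()
    n_dropped = 0
    for row in df.itertuples(index=False):
        if format == "airr":
            cdr3 = str(getattr(row, "junction_aa"))
            chain = _LOCUS_TO_CHAIN.get(str(getattr(row, "locus")).strip().upper())
            v_family = normalize_v_family(str(getattr(row, "v_call")))
            if chain is None:
                n_dropped += 1
                continue
        else:
            chain = str(getattr(row, "chain")).strip().lower()
            cdr3 = str(getattr(row, "cdr3_aa"))
            v_family = normalize_v_family(str(getattr(row, "v_family")))
        if not _productive(cdr3):
            n_dropped += 1
            continue
        try:
            clonotypes.add(Clonotype(chain=chain, cdr3_aa=cdr3, v_family=v_family))
        except ValueError:
            n_dropped += 1
    if n_dropped:
        logger.info("%s: dropped %d non-productive/malformed rows", path, n_dropped)
    if not clonotypes:
        warnings.warn(f"{path}: zero productive clonotypes for donor {donor_id!r}")
    return Donor(
        donor_id=donor_id, cohort=cohort, clonotypes=frozenset(clonotypes), has_alpha=has_alpha
    )


def write_clonotype_table(donor: Donor, path) -> None:
    """Write a donor's clonotypes in the simple TSV format (sorted, stable)."""
    rows = sorted((c.chain, c.cdr3_aa, c.v_family) for c in donor.clonotypes)
    pd.DataFrame(rows, columns=list(_SIMPLE_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_hla_table(path, strict: bool = False) -> Dict[str, Set[HlaAllele]]:
    """Read a donor -> HLA typing table.

    The table (TSV or CSV, sniffed from the extension) must have a
    ``donor_id`` column plus either a single ``alleles`` column holding a
    comma-separated list of codes, or wide columns each holding one allele
    code (empty cells allowed).  Codes are normalized to 4-digit resolution.

    With ``strict=True`` donors with incomplete typing — no allele at one of
    the class-I loci A/B/C — are excluded (logged), mirroring the usual
    cohort curation rule.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "donor_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'donor_id'")
    out: Dict[str, Set[HlaAllele]] = {}
    for _, row in df.iterrows():
        donor = str(row["donor_id"])
        tokens: List[str] = []
        if "alleles" in df.columns:
            cell = row["alleles"]
            if isinstance(cell, str):
                tokens = [t for t in cell.split(",") if t.strip()]
        else:
            for col in df.columns:
                if col == "donor_id":
                    continue
                cell = row[col]
                if isinstance(cell, str) and cell.strip():
                    tokens.append(cell)
        alleles = {HlaAllele.parse(t) for t in tokens}
        for locus in CLASS_I_LOCI:
            n = sum(1 for a in alleles if a.locus == locus)
            if n > 2:
                raise ValueError(
                    f"{path}: donor {donor}: {n} alleles at class-I locus {locus} (max 2)"
                )
        if strict and any(
            not any(a.locus == locus for a in alleles) for locus in CLASS_I_LOCI
        ):
            logger.info("excluding donor %s: incomplete class-I typing", donor)
            continue
        out[donor] = alleles
    return out


def write_hla_table(typings: Dict[str, Iterable[HlaAllele]], path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    rows = [
        {"donor_id": d, "alleles": ",".join(a.code for a in sorted(set(al)))}
        for d, al in sorted(typings.items())
    ]
    pd.DataFrame(rows, columns=["donor_id", "alleles"]).to_csv(path, sep=sep, index=False)


def assemble_cohort(
    donors: Iterable[Donor],
    typings: Optional[Dict[str, Set[HlaAllele]]] = None,
    name: str = "cohort",
) -> Cohort:
    """Combine donors with an optional typing table into a Cohort.

    Duplicate donor ids (e.g. repeat samples from the same donor) keep the
    first sample encountered; later ones are excluded and logged.
    """
    seen: Dict[str, Donor] = {}
    for d in donors:
        if d.donor_id in seen:
            logger.info("excluding duplicate sample for donor %s", d.donor_id)
            continue
        if typings is not None and d.donor_id in typings:
            d = Donor(
                donor_id=d.donor_id,
                cohort=d.cohort,
                clonotypes=d.clonotypes,
                has_alpha=d.has_alpha,
                hla=frozenset(typings[d.donor_id]),
            )
        seen[d.donor_id] = d
    return Cohort(donors=list(seen.values()), name=name)


def occurrence_matrix(
    cohort: Cohort, min_publicness: int = 3
) -> Tuple[List[Clonotype], pd.DataFrame]:
    """Donor x clonotype binary presence matrix restricted to public clonotypes.

    Only clonotypes present in at least ``min_publicness`` donors of the
    given (possibly merged) cohort are retained.  Presence is binary; clone
    abundance is ignored.  Columns are sorted by (chain, v_family, cdr3_aa)
    and rows follow cohort order, so output is deterministic.
    """
    if min_publicness < 1:
        raise ValueError("min_publicness must be >= 1")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    counts: Dict[Clonotype, int] = {}
    for d in cohort:
        for c in d.clonotypes:
            counts[c] = counts.get(c, 0) + 1
    kept = sorted(
        (c for c, n in counts.items() if n >= min_publicness),
        key=lambda c: (c.chain, c.v_family, c.cdr3_aa),
    )
    col_index = {c: j for j, c in enumerate(kept)}
    mat = np.zeros((len(cohort), len(kept)), dtype=np.int8)
    donor_ids = []
    for i, d in enumerate(cohort):
        donor_ids.append(d.donor_id)
        for c in d.clonotypes:
            j = col_index.get(c)
            if j is not None:
                mat[i, j] = 1
    df = pd.DataFrame(mat, index=pd.Index(donor_ids, name="donor_id"), columns=range(len(kept)))
    return kept, df
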