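"""Readers and writers for the pipeline's tabular formats.

All tables are plain TSV. Variant/prediction tables follow a dbNSFP-style
layout: one row per variant, one column per predictor, blank cells for
missing annotations. A *dialect* maps canonical column names to the names
used in a particular file, so externally produced tables can be ingested
without renaming columns by hand.
"""
from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .types import (PREDICTORS, Consequence, GeneEvidence, Genotype,
                    PredictionProfile, TrioGenotype, VariantRecord)

#: Canonical column names of a variant/prediction table. A dialect may remap
#: any subset of these to file-specific names.
VARIANT_COLUMNS = ("variant_id", "gene", "consequence", "chrom", "pos", "ref",
                   "alt", "hgvs_c", "hgvs_p", "rsid", "maf_nfe",
                   "clinvar_lp_for_trait", "ada", "cadd", "dann",
                   "mutpred_lof") + PREDICTORS

_MANDATORY = ("variant_id", "gene", "consequence")

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"row {row}: malformed boolean {value!r} in {column}")


def _parse_float(value: str, column: str, row: int) -> Optional[float]:
    v = value.strip()
    if v == "":
        return None
    try:
        return float(v)
    except ValueError:
        raise ValueError(
            f"row {row}: malformed numeric {value!r} in column {column}"
        ) from None


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_variant_table(
    path,
    dialect: Optional[Mapping[str, str]] = None,
) -> List[Tuple[VariantRecord, PredictionProfile]]:
    """Read an annotated variant table into (record, profile) pairs.

    Parameters
    ----------
    path : path-like
        TSV file with one row per variant.
    dialect : mapping, optional
        Maps canonical column names (see ``VARIANT_COLUMNS``) to the file's
        column names. Unmapped canonical names are looked up verbatim.

    Returns rows in file order. Missing cells become absent optional fields.
    Raises ``ValueError`` for unknown consequence strings, malformed numerics
    and duplicate variant ids, naming the offending row.
    """
    dialect = dict(dialect or {})
    frame = _read_tsv(path)

    def col(name: str) -> Optional[str]:
        actual = dialect.get(name, name)
        return actual if actual in frame.columns else None

    for name in _MANDATORY:
        if col(name) is None:
            raise ValueError(
                f"mandatory column {name!r} not resolvable in {path}")

    out: List[Tuple[VariantRecord, PredictionProfile]] = []
    seen: Dict[str, int] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        # positional access is more robust than attribute names pandas munges
        values = {name: (row[frame.columns.get_loc(col(name))]
                         if col(name) is not None else "")
                  for name in VARIANT_COLUMNS}
        vid = values["variant_id"].strip()
        if vid in seen:
            raise ValueError(
                f"row {i}: duplicate variant_id {vid!r} (first at row "
                f"{seen[vid]})")
        seen[vid] = i
        csq_raw = values["consequence"].strip()
        try:
            csq = Consequence(csq_raw)
        except ValueError:
            raise ValueError(
                f"row {i}: unknown consequence {csq_raw!r}") from None
        pos = values["pos"].strip()
        record = VariantRecord(
            variant_id=vid,
            gene=values["gene"].strip(),
            consequence=csq,
            chrom=values["chrom"].strip() or None,
            pos=int(pos) if pos else None,
            ref=values["ref"].strip() or None,
            alt=values["alt"].strip() or None,
            hgvs_c=values["hgvs_c"].strip() or None,
            hgvs_p=values["hgvs_p"].strip() or None,
            rsid=values["rsid"].strip() or None,
            maf_nfe=_parse_float(values["maf_nfe"], "maf_nfe", i),
            clinvar_lp_for_trait=_parse_bool(
                values["clinvar_lp_for_trait"], "clinvar_lp_for_trait", i),
        )
        calls: Dict[str, object] = {}
        for tool in PREDICTORS:
            cell = values[tool].strip()
            if cell == "":
                continue
            calls[tool] = (_parse_float(cell, tool, i)
                           if tool == "REVEL" else cell)
        profile = PredictionProfile(
            variant_id=vid,
            calls=calls,
            cadd_phred=_parse_float(values["cadd"], "cadd", i),
            dann=_parse_float(values["dann"], "dann", i),
            ada=_parse_float(values["ada"], "ada", i),
            mutpred_lof=_parse_float(values["mutpred_lof"], "mutpred_lof", i),
        )
        out.append((record, profile))
    return out


def write_variant_table(
    pairs: Sequence[Tuple[VariantRecord, PredictionProfile]],
    path,
) -> None:
    """Write (record, profile) pairs as a canonical-dialect TSV.

    Round-trips through :func:`read_variant_table` without loss.
    """
    rows = []
    for record, profile in pairs:
        row = {
            "variant_id": record.variant_id,
            "gene": record.gene,
            "consequence": record.consequence.value,
            "chrom": record.chrom or "",
            "pos": "" if record.pos is None else str(record.pos),
            "ref": record.ref or "",
            "alt": record.alt or "",
            "hgvs_c": record.hgvs_c or "",
            "hgvs_p": record.hgvs_p or "",
            "rsid": record.rsid or "",
            "maf_nfe": _fmt(record.maf_nfe),
            "clinvar_lp_for_trait": str(record.clinvar_lp_for_trait).lower(),
            "ada": _fmt(profile.ada),
            "cadd": _fmt(profile.cadd_phred),
            "dann": _fmt(profile.dann),
            "mutpred_lof": _fmt(profile.mutpred_lof),
        }
        for tool in PREDICTORS:
            call = profile.calls.get(tool, "")
            row[tool] = _fmt(call) if tool == "REVEL" and call != "" else call
        rows.append(row)
    _write_rows(path, list(VARIANT_COLUMNS), rows)


def _fmt(value) -> str:
    if value is None or value == "":
        return ""
    return repr(float(value))


def _write_rows(path, columns: List[str], rows: List[dict]) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t",
                                lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


TRIO_COLUMNS = ("family_id", "proband_id", "variant_id", "gt_proband",
                "gt_father", "gt_mother", "father_affected",
                "mother_affected", "parentage_verified")


def read_trio_table(path) -> List[TrioGenotype]:
    """Read a trio genotype table (one row per variant x proband)."""
    frame = _read_tsv(path)
    missing = [c for c in TRIO_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trio table missing columns: {missing}")
    out = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        try:
            out.append(TrioGenotype(
                variant_id=row["variant_id"],
                family_id=row["family_id"],
                proband_id=row["proband_id"],
                proband_gt=Genotype(row["gt_proband"]),
                father_gt=Genotype(row["gt_father"]),
                mother_gt=Genotype(row["gt_mother"]),
                father_affected=_parse_bool(
                    row["father_affected"], "father_affected", i),
                mother_affected=_parse_bool(
                    row["mother_affected"], "mother_affected", i),
                parentage_verified=_parse_bool(
                    row["parentage_verified"], "parentage_verified", i),
            ))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
    return out


def write_trio_table(trios: Sequence[TrioGenotype], path) -> None:
    rows = [{
        "family_id": t.family_id,
        "proband_id": t.proband_id,
        "variant_id": t.variant_id,
        "gt_proband": t.proband_gt.value,
        "gt_father": t.father_gt.value,
        "gt_mother": t.mother_gt.value,
        "father_affected": str(t.father_affected).lower(),
        "mother_affected": str(t.mother_affected).lower(),
        "parentage_verified": str(t.parentage_verified).lower(),
    } for t in trios]
    _write_rows(path, list(TRIO_COLUMNS), rows)


EVIDENCE_COLUMNS = ("gene", "pli", "domino_class", "domino_ad_prob",
                    "ofc_syndromic", "ofc_nonsyndromic", "ofc_ko_mouse")


def read_gene_evidence(path) -> Dict[str, GeneEvidence]:
    """Read a per-gene evidence table keyed by gene symbol."""
    frame = _read_tsv(path)
    missing = [c for c in EVIDENCE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"evidence table missing columns: {missing}")
    out: Dict[str, GeneEvidence] = {}
    for i, row in enumerate(frame.to_dict("records"), start=1):
        gene = row["gene"].strip()
        if gene in out:
            raise ValueError(f"row {i}: duplicate gene {gene!r}")
        out[gene] = GeneEvidence(
            gene=gene,
            pli=_parse_float(row["pli"], "pli", i),
            domino_class=row["domino_class"],
            domino_ad_prob=_parse_float(
                row["domino_ad_prob"], "domino_ad_prob", i),
            ofc_syndromic=_parse_bool(row["ofc_syndromic"],
                                      "ofc_syndromic", i),
            ofc_nonsyndromic=_parse_bool(row["ofc_nonsyndromic"],
                                         "ofc_nonsyndromic", i),
            ofc_ko_mouse=_parse_bool(row["ofc_ko_mouse"],
                                     "ofc_ko_mouse", i),
        )
    return out


def write_gene_evidence(evidence: Mapping[str, GeneEvidence], path) -> None:
    rows = [{
        "gene": e.gene,
        "pli": repr(e.pli),
        "domino_class": e.domino_class.value,
        "domino_ad_prob": repr(e.domino_ad_prob),
        "ofc_syndromic": str(e.ofc_syndromic).lower(),
        "ofc_nonsyndromic": str(e.ofc_nonsyndromic).lower(),
        "ofc_ko_mouse": str(e.ofc_ko_mouse).lower(),
    } for e in evidence.values()]
    _write_rows(path, list(EVIDENCE_COLUMNS), rows)


def write_results_table(records: Sequence, path,
                        columns: Optional[Sequence[str]] = None) -> None:
    """Write a homogeneous sequence of dataclasses or dicts as TSV.

    Column order is the (shared) field order of the first record; all records
    must share the same schema. An empty sequence writes a header-only file,
    for which ``columns`` must be given.
    """
    if not records:
        if columns is None:
            raise ValueError("empty sequence needs explicit columns for a "
                             "header-only file")
        _write_rows(path, list(columns), [])
        return
    first = records[0]
    if dataclasses.is_dataclass(first):
        columns = [f.name for f in dataclasses.fields(first)]
        rows = []
        for rec in records:
            d = dataclasses.asdict(rec)
            rows.append({k: _cell(v) for k, v in d.items()})
    else:
        columns = list(first.keys())
        rows = [{k: _cell(v) for k, v in rec.items()} for rec in records]
    _write_rows(path, columns, rows)


def _cell(value) -> str:
    import enum as _enum
    if value is None:
        return ""
    if isinstance(value, _enum.Enum):
        return value.value
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_gene_list(path) -> List[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path) -> List[Tuple[str, str, List[str]]]:
    """Read a GMT gene-set file: (set_id, description, genes) per line."""
    sets = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {i}: need id, description, >=1 gene")
        sets.append((parts[0], parts[1], [g for g in parts[2:] if g]))
    return sets


def write_gmt(sets: Sequence[Tuple[str, str, Sequence[str]]], path) -> None:
    lines = ["\t".join([sid, desc, *genes]) for sid, desc, genes in sets]
    Path(path).write_text("\n".join(lines) + "\n")
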