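"""Readers and writers: annotated variant tables, VCF, GMT gene sets, BED
blacklists, and TSV/JSON round-tripping of pipeline result objects.

The canonical interchange format is a tab-separated variant table with a
'#'-prefixed header, one row per mutation x sample observation.  Rows sharing
(patient, chrom, pos, ref, alt) are merged into one :class:`MutationRecord`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from intervaltree import IntervalTree

from .model import (
    Consequence,
    CurationFlag,
    GeneSetCollection,
    MutationRecord,
    Patient,
    PatientCohort,
    PipelineError,
    RegionClass,
    RowValidationError,
    SampleObservation,
    SchemaError,
    Stage,
    build_cohort,
)

__all__ = [
    "TableDialect",
    "read_variant_table",
    "write_variant_table",
    "read_gmt",
    "read_bed_blacklist",
    "read_vcf",
    "write_results",
    "read_selection_results",
    "read_enrichment_results",
    "read_category_assignments",
]

MANDATORY_COLUMNS = (
    "patient",
    "sample",
    "stage",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_reads",
    "region_class",
    "consequence",
)

OPTIONAL_COLUMNS = ("gene", "cdna_change", "aa_change", "pop_af", "flags")


@dataclass
class TableDialect:
    """Maps the canonical column names onto the columns of a concrete table."""

    columns: dict = field(default_factory=dict)  # canonical name -> actual name
    sep: str = "\t"

    def actual(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def _read_tsv(path, sep="\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    # '#'-prefixed header: strip the marker from the first column name
    first = df.columns[0]
    if first.startswith("#"):
        df = df.rename(columns={first: first.lstrip("#").strip()})
    return df


def read_variant_table(path, dialect: Optional[TableDialect] = None) -> PatientCohort:
    """Read an annotated variant table into a validated cohort.

    One row per (mutation, sample); rows for the same mutation across samples
    are merged into a single record.  Merging is order-independent.
    """
    dialect = dialect or TableDialect()
    df = _read_tsv(path, sep=dialect.sep)
    colmap = {c: dialect.actual(c) for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS}
    for canonical in MANDATORY_COLUMNS:
        if colmap[canonical] not in df.columns:
            raise SchemaError(
                f"variant table {path} is missing mandatory column "
                f"{colmap[canonical]!r}"
            )

    records: dict = {}
    order: list = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        # pandas itertuples mangles names; index positionally instead
        vals = {c: row[df.columns.get_loc(colmap[c])] for c in MANDATORY_COLUMNS}
        opt = {
            c: row[df.columns.get_loc(colmap[c])]
            for c in OPTIONAL_COLUMNS
            if colmap[c] in df.columns
        }
        try:
            depth = int(vals["depth"])
            alt_reads = int(vals["alt_reads"])
            pos = int(vals["pos"])
        except ValueError as exc:
            raise RowValidationError(f"non-integer numeric field: {exc}", row=i)
        key = (vals["patient"], vals["chrom"], pos, vals["ref"], vals["alt"])
        try:
            if key not in records:
                pop_af_raw = opt.get("pop_af", "")
                pop_af = float(pop_af_raw) if pop_af_raw not in ("", ".", "NA") else None
                flags_raw = opt.get("flags", "")
                flags = {
                    CurationFlag(f) for f in str(flags_raw).split(",") if f and f != "."
                }
                records[key] = MutationRecord(
                    patient_id=str(vals["patient"]),
                    chrom=str(vals["chrom"]),
                    pos=pos,
                    ref=str(vals["ref"]),
                    alt=str(vals["alt"]),
                    gene=str(opt.get("gene", "")),
                    region_class=RegionClass(str(vals["region_class"]).upper()),
                    consequence=Consequence(str(vals["consequence"]).upper()),
                    cdna_change=str(opt.get("cdna_change", "")),
                    aa_change=str(opt.get("aa_change", "")),
                    pop_af=pop_af,
                    curation_flags=flags,
                )
                order.append(key)
            records[key].add_observation(
                SampleObservation(
                    sample_id=str(vals["sample"]),
                    stage=Stage(str(vals["stage"]).upper()),
                    depth=depth,
                    alt_reads=alt_reads,
                )
            )
        except RowValidationError as exc:
            if exc.row is None:
                raise RowValidationError(str(exc), row=i) from exc
            raise
        except ValueError as exc:
            raise RowValidationError(str(exc), row=i) from exc
    # deterministic order independent of input row order
    order.sort()
    return build_cohort(records[k] for k in order)


def write_variant_table(cohort: PatientCohort, path) -> None:
    """Write the canonical one-row-per-observation table ('#'-header TSV)."""
    rows = []
    for mut in cohort.mutations:
        for obs in mut.observations.values():
            rows.append(
                {
                    "patient": mut.patient_id,
                    "sample": obs.sample_id,
                    "stage": obs.stage.value,
                    "chrom": mut.chrom,
                    "pos": mut.pos,
                    "ref": mut.ref,
                    "alt": mut.alt,
                    "gene": mut.gene,
                    "region_class": mut.region_class.value,
                    "consequence": mut.consequence.value,
                    "depth": obs.depth,
                    "alt_reads": obs.alt_reads,
                    "pop_af": "" if mut.pop_af is None else repr(mut.pop_af),
                    "cdna_change": mut.cdna_change,
                    "aa_change": mut.aa_change,
                    "flags": ",".join(sorted(f.value for f in mut.curation_flags)),
                }
            )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if len(df) == 0:
            fh.write("#" + "\t".join(MANDATORY_COLUMNS + OPTIONAL_COLUMNS) + "\n")
            return
        fh.write("#")
        df.to_csv(fh, sep="\t", index=False)


def read_gmt(path, collection_size_override: Optional[int] = None) -> GeneSetCollection:
    """Read a GMT gene-set file (set name, description, member genes...).

    ``collection_size_override`` sets the multiple-testing family size m when
    the file holds only a displayed subset of a larger tested collection.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PipelineError(
                    f"{path}: malformed GMT line {lineno} "
                    f"(expected >=3 tab-separated fields, got {len(fields)})"
                )
            name, _desc, *genes = fields
            sets[name] = {g.strip().upper() for g in genes if g.strip()}
    import os

    return GeneSetCollection(
        name=os.path.basename(str(path)),
        sets=sets,
        collection_size=collection_size_override,
    )


def read_bed_blacklist(path) -> dict:
    """Read a BED blacklist into per-chromosome interval trees.

    BED is 0-based half-open; internally intervals are 1-based closed, so a
    BED line ``chr1 9 20`` covers 1-based positions 10..20.
    """
    trees: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PipelineError(f"{path}: malformed BED line {lineno}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            # 1-based closed [start+1, end]; IntervalTree ends are exclusive
            trees.setdefault(chrom, IntervalTree()).addi(start + 1, end + 1)
    return trees


def in_blacklist(trees: Optional[dict], chrom: str, pos: int) -> bool:
    if not trees:
        return False
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlaps(pos))


def read_vcf(path, sample_map: dict, patient_id: Optional[str] = None,
             gene_info: str = "GENE", consequence_info: str = "CSQ",
             region_info: str = "REGION", pop_af_info: str = "AF_POP") -> PatientCohort:
    """Ingest raw calls from a VCF 4.x file.

    ``sample_map`` maps VCF sample names to ``(patient_id, Stage)``; depth and
    alt-read counts come from the per-sample FORMAT fields (AD preferred, else
    DP).  Annotation INFO keys are remapped via the keyword arguments and fall
    back to OTHER/EXONIC when absent, since caller outputs are heterogeneous.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = vcf.samples
    for s in names:
        if s not in sample_map:
            raise SchemaError(f"VCF sample {s!r} missing from sample_map")
    mutations = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise PipelineError(
                f"multi-allelic site {var.CHROM}:{var.POS} not supported; "
                "decompose first"
            )
        info = dict(var.INFO)
        try:
            consequence = Consequence(str(info.get(consequence_info, "OTHER")).upper())
        except ValueError:
            consequence = Consequence.OTHER
        try:
            region = RegionClass(str(info.get(region_info, "EXONIC")).upper())
        except ValueError:
            region = RegionClass.OTHER
        pop_af = info.get(pop_af_info)
        rec = MutationRecord(
            patient_id=patient_id or sample_map[names[0]][0],
            chrom=var.CHROM,
            pos=var.POS,
            ref=var.REF,
            alt=var.ALT[0],
            gene=str(info.get(gene_info, "")),
            region_class=region,
            consequence=consequence,
            pop_af=float(pop_af) if pop_af is not None else None,
        )
        def fmt(field):
            try:
                return var.format(field)
            except KeyError:
                return None

        ad = fmt("AD")
        depths = fmt("DP")
        for i, s in enumerate(names):
            pid, stage = sample_map[s]
            if ad is not None:
                ref_reads, alt_reads = int(ad[i][0]), int(ad[i][1])
                depth = ref_reads + alt_reads
            else:
                depth = int(depths[i][0]) if depths is not None else 0
                alt_reads = 0
            rec.add_observation(
                SampleObservation(sample_id=s, stage=Stage(stage), depth=max(depth, 0),
                                  alt_reads=max(alt_reads, 0))
            )
        mutations.append(rec)
    return build_cohort(mutations)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

SELECTION_COLUMNS = ("label", "ns", "s", "ratio", "p_value", "driver_estimate",
                     "null_ns_fraction")
ENRICHMENT_COLUMNS = ("set_name", "set_size", "query_size", "overlap",
                      "overlap_genes", "universe_size", "p_value", "q_value", "rank")
CATEGORY_COLUMNS = ("patient", "chrom", "pos", "ref", "alt", "gene", "category",
                    "stages_present")


def _selection_rows(results) -> list:
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label,
                "ns": r.ns,
                "s": r.s,
                "ratio": "" if r.s == 0 else repr(r.ns / r.s),
                "p_value": repr(r.p_value),
                "driver_estimate": r.driver_estimate,
                "null_ns_fraction": repr(r.null_ns_fraction),
            }
        )
    return rows


def write_results(obj, path, format: str = "TSV") -> None:
    """Write a pipeline result object (or list) as TSV or JSON.

    Supported: SelectionTestResult, EnrichmentResult lists, CategoryAssignment
    lists.  TSV output round-trips losslessly through the matching reader.
    """
    from .enrichment import EnrichmentResult
    from .progression import CategoryAssignment
    from .selection import SelectionTestResult

    items = obj if isinstance(obj, (list, tuple)) else [obj]
    fmt = format.upper()
    if fmt not in ("TSV", "JSON"):
        raise PipelineError(f"unsupported output format {format!r}")

    if all(isinstance(x, SelectionTestResult) for x in items):
        rows = _selection_rows(items)
        columns = SELECTION_COLUMNS
    elif all(isinstance(x, EnrichmentResult) for x in items):
        rows = [
            {
                "set_name": r.set_name,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "overlap": r.overlap,
                "overlap_genes": ",".join(r.overlap_genes),
                "universe_size": r.universe_size,
                "p_value": repr(r.p_value),
                "q_value": repr(r.q_value),
                "rank": r.rank,
            }
            for r in items
        ]
        columns = ENRICHMENT_COLUMNS
    elif all(isinstance(x, CategoryAssignment) for x in items):
        rows = [
            {
                "patient": a.key[0],
                "chrom": a.key[1],
                "pos": a.key[2],
                "ref": a.key[3],
                "alt": a.key[4],
                "gene": a.gene,
                "category": a.category.value,
                "stages_present": ",".join(
                    st.value for st in Stage if a.stage_presence.get(st, False)
                ),
            }
            for a in items
        ]
        columns = CATEGORY_COLUMNS
    else:
        raise PipelineError(
            f"unsupported result type {type(items[0]).__name__!r} for write_results"
        )

    if fmt == "JSON":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        df = pd.DataFrame(rows, columns=list(columns))
        df.to_csv(path, sep="\t", index=False)


def _load_rows(path, format: str) -> list:
    if format.upper() == "JSON":
        with open(path) as fh:
            return json.load(fh)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df.to_dict(orient="records")


def read_selection_results(path, format: str = "TSV") -> list:
    from .selection import SelectionTestResult

    out = []
    for row in _load_rows(path, format):
        ns, s = int(row["ns"]), int(row["s"])
        out.append(
            SelectionTestResult(
                label=str(row["label"]),
                ns=ns,
                s=s,
                p_value=float(row["p_value"]),
                driver_estimate=int(row["driver_estimate"]),
                null_ns_fraction=float(row["null_ns_fraction"]),
            )
        )
    return out


def read_enrichment_results(path, format: str = "TSV") -> list:
    from .enrichment import EnrichmentResult

    out = []
    for row in _load_rows(path, format):
        genes = str(row["overlap_genes"])
        out.append(
            EnrichmentResult(
                set_name=str(row["set_name"]),
                set_size=int(row["set_size"]),
                query_size=int(row["query_size"]),
                overlap=int(row["overlap"]),
                overlap_genes=tuple(g for g in genes.split(",") if g),
                universe_size=int(row["universe_size"]),
                p_value=float(row["p_value"]),
                q_value=float(row["q_value"]),
                rank=int(row["rank"]),
            )
        )
    return out


def read_category_assignments(path, format: str = "TSV") -> list:
    from .progression import Category, CategoryAssignment

    out = []
    for row in _load_rows(path, format):
        present = {
            Stage(s) for s in str(row["stages_present"]).split(",") if s
        }
        out.append(
            CategoryAssignment(
                key=(
                    str(row["patient"]),
                    str(row["chrom"]),
                    int(row["pos"]),
                    str(row["ref"]),
                    str(row["alt"]),
                ),
                gene=str(row.get("gene", "")),
                category=Category(str(row["category"])),
                stage_presence={st: (st in present) for st in Stage},
            )
        )
    return out
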