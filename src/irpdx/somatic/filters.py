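"""Somatic variant filter cascade on multi-sample call tables.

The cascade mirrors a tumour/normal exome workflow in which per-tumour
calls are first screened against the matched normal (candidate filter),
candidates are re-called jointly across all samples of a patient and
screened on joint-call quality (joint filter), and finally variants whose
maximum purity-adjusted allele fraction across samples falls below 0.05 are
discarded as residual contamination.  Surviving variants are binarised into
a sample-by-variant mutation matrix with an all-zero outgroup row
(germline reference) for phylogeny.

Call tables are long-form :class:`pandas.DataFrame` objects with one row
per variant per sample and columns ``chrom, pos, ref, alt, sample, NR, NV,
GT, GQ, flag`` (NR = total reads, NV = variant reads).  A per-variant audit
trail names the first rule each rejected variant failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

OUTGROUP_LABEL = "outgroup"

#: Joint-call flags accepted by the joint filter.
ALLOWED_JOINT_FLAGS = frozenset({"PASS", "alleleBias", "QD", "Q20"})

#: chr1-22, X, Y with and without the "chr" prefix.
CANONICAL_CHROMS = frozenset(
    [f"chr{i}" for i in list(range(1, 23)) + ["X", "Y"]]
    + [str(i) for i in list(range(1, 23)) + ["X", "Y"]]
)

REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "sample", "NR", "NV", "GT", "GQ", "flag")

NONREF_GENOTYPES = ("0/1", "1/1", "0|1", "1|0", "1|1")
REF_GENOTYPES = ("0/0", "0|0")


def variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


@dataclass
class VariantTable:
    """Joint variant calls for one patient.

    Parameters
    ----------
    calls
        Long-form table, one row per (variant, sample), with the columns in
        :data:`REQUIRED_COLUMNS`.
    normal
        Name of the matched-normal sample (must appear in ``calls``).
    purity
        Tumour purity per sample, each in (0, 1].  The normal sample may be
        omitted (treated as purity 1).
    """

    calls: pd.DataFrame
    normal: str
    purity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.calls.columns]
        if missing:
            raise ValueError(f"call table missing columns: {missing}")
        if (self.calls["NV"] > self.calls["NR"]).any():
            raise ValueError("NV exceeds NR in call table")
        samples = set(self.calls["sample"].unique())
        if self.normal not in samples:
            raise ValueError(f"normal sample {self.normal!r} not present in call table")
        for s, p in self.purity.items():
            if not (0 < p <= 1):
                raise ValueError(f"purity for sample {s!r} must lie in (0, 1], got {p}")
        calls = self.calls.copy()
        calls["variant_id"] = [
            variant_id(c, p, r, a)
            for c, p, r, a in zip(calls["chrom"], calls["pos"], calls["ref"], calls["alt"])
        ]
        self.calls = calls

    @property
    def tumour_samples(self) -> list[str]:
        return sorted(s for s in self.calls["sample"].unique() if s != self.normal)

    @property
    def variant_ids(self) -> list[str]:
        return list(dict.fromkeys(self.calls["variant_id"]))


@dataclass
class FilterResult:
    """Outcome of the full cascade with a per-variant audit trail."""

    candidates: list[str]
    retained: list[str]
    final: list[str]
    audit: pd.DataFrame  # variant_id, stage, first_failed_rule (NA if passed)
    vafadj: pd.DataFrame  # variant_id x sample VAFadj for final variants
    matrix: pd.DataFrame  # samples (+outgroup) x final variants, binary


def _is_nonref(gt: pd.Series) -> pd.Series:
    return gt.isin(NONREF_GENOTYPES)


def _is_ref(gt: pd.Series) -> pd.Series:
    return gt.isin(REF_GENOTYPES)


def candidate_filter(table: VariantTable, audit: dict[str, str] | None = None) -> list[str]:
    """Screen per-tumour calls against the matched normal.

    A variant is a candidate if in at least one tumour sample the call is
    flagged PASS with depth >= 10 in both that tumour and the normal,
    >= 3 variant reads in the tumour, 0 variant reads in the normal, a
    reference genotype in the normal and a non-reference genotype in the
    tumour.  Candidates from all tumour samples are merged into one list.

    When ``audit`` is supplied, rejected variants are annotated with the
    first rule (in the documented order) at which no tumour sample was left.
    """
    calls = table.calls
    normal = calls[calls["sample"] == table.normal].set_index("variant_id")
    if normal.empty:
        raise ValueError("no records for the normal sample")
    tumour = calls[calls["sample"] != table.normal].copy()
    if tumour.empty:
        raise ValueError("no tumour samples in call table")

    n_nr = tumour["variant_id"].map(normal["NR"])
    n_nv = tumour["variant_id"].map(normal["NV"])
    n_gt = tumour["variant_id"].map(normal["GT"])

    # Rules in audit order; each is evaluated per tumour-sample record.
    rules = [
        ("caller_flag_not_PASS", tumour["flag"].eq("PASS")),
        ("tumour_depth_lt_10", tumour["NR"] >= 10),
        ("normal_depth_lt_10", n_nr >= 10),
        ("tumour_variant_reads_lt_3", tumour["NV"] >= 3),
        ("normal_variant_reads_gt_0", n_nv == 0),
        ("normal_genotype_not_ref", _is_ref(n_gt)),
        ("tumour_genotype_ref", _is_nonref(tumour["GT"])),
    ]
    alive = pd.Series(True, index=tumour.index)
    surviving: dict[str, set] = {}
    for name, ok in rules:
        before = set(tumour.loc[alive, "variant_id"])
        alive &= ok.fillna(False)
        after = set(tumour.loc[alive, "variant_id"])
        if audit is not None:
            for vid in before - after:
                surviving.setdefault(vid, name)
    candidates = [v for v in table.variant_ids if v in set(tumour.loc[alive, "variant_id"])]
    if audit is not None:
        for vid in table.variant_ids:
            if vid not in candidates:
                audit[vid] = "candidate:" + surviving.get(vid, "no_tumour_record")
    return candidates


def joint_filter(
    table: VariantTable,
    candidates: list[str],
    audit: dict[str, str] | None = None,
    allowed_flags: frozenset[str] = ALLOWED_JOINT_FLAGS,
    canonical: frozenset[str] = CANONICAL_CHROMS,
) -> list[str]:
    """Joint-recall quality filter across all samples.

    Retains candidates whose joint-call flag is one of PASS, alleleBias, QD
    or Q20, on canonical chromosomes, with NR > 10 and GQ > 10 in *all*
    samples (strict inequality), a reference genotype in the normal and a
    non-reference genotype in at least one tumour sample.
    """
    calls = table.calls
    samples = sorted(calls["sample"].unique())
    by_variant = calls.set_index(["variant_id", "sample"]).sort_index()
    retained = []
    for vid in candidates:
        try:
            recs = by_variant.loc[vid]
        except KeyError:
            raise ValueError(f"candidate {vid} has no joint-call records")
        missing = set(samples) - set(recs.index)
        if missing:
            raise ValueError(
                f"candidate {vid} missing joint-call record for sample(s) {sorted(missing)}"
            )
        flag = recs["flag"].iloc[0]
        chrom = str(vid.split(":")[0])
        normal = recs.loc[table.normal]
        tumours = recs.drop(index=table.normal)
        checks = [
            ("flag_not_allowed", flag in allowed_flags),
            ("non_canonical_chromosome", chrom in canonical),
            ("NR_not_gt_10_in_all_samples", bool((recs["NR"] > 10).all())),
            ("GQ_not_gt_10_in_all_samples", bool((recs["GQ"] > 10).all())),
            ("normal_genotype_not_ref", normal["GT"] in REF_GENOTYPES),
            ("no_tumour_nonref_genotype", bool(_is_nonref(tumours["GT"]).any())),
        ]
        failed = next((name for name, ok in checks if not ok), None)
        if failed is None:
            retained.append(vid)
        elif audit is not None:
            audit[vid] = "joint:" + failed
    return retained


def compute_vafadj(table: VariantTable, variants: list[str]) -> pd.DataFrame:
    """Purity-adjusted VAF per variant and sample.

    VAF = NV/NR, VAFadj = VAF / sample purity.  Samples with NR = 0
    contribute no VAFadj (NaN).  The normal, if no purity is given, is
    treated as purity 1.
    """
    calls = table.calls[table.calls["variant_id"].isin(variants)]
    samples = sorted(calls["sample"].unique())
    for s in samples:
        if s != table.normal and s not in table.purity:
            raise ValueError(f"purity missing for sample {s!r}")
    wide_nv = calls.pivot_table(index="variant_id", columns="sample", values="NV")
    wide_nr = calls.pivot_table(index="variant_id", columns="sample", values="NR")
    vaf = wide_nv / wide_nr.where(wide_nr > 0)
    purities = pd.Series({s: table.purity.get(s, 1.0) for s in samples})
    vafadj = vaf / purities
    return vafadj.reindex(variants)


def vafadj_filter(
    table: VariantTable,
    retained: list[str],
    threshold: float = 0.05,
    audit: dict[str, str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop variants whose max VAFadj across samples is below ``threshold``.

    Returns the surviving variant list and the full VAFadj table for them.
    """
    if not retained:
        return [], pd.DataFrame()
    vafadj = compute_vafadj(table, retained)
    max_adj = vafadj.max(axis=1, skipna=True)
    keep = max_adj >= threshold
    final = [v for v in retained if keep.get(v, False)]
    if audit is not None:
        for v in retained:
            if v not in final:
                audit[v] = "vafadj:max_vafadj_below_threshold"
    return final, vafadj.loc[final]


def binarize(table: VariantTable, final: list[str]) -> pd.DataFrame:
    """Binary mutation matrix over tumour samples plus an all-zero outgroup.

    A sample is scored 1 for a variant if it carries any variant reads
    (NV >= 1) for it.
    """
    if not final:
        raise ValueError("no variants survived filtering; nothing to binarise")
    calls = table.calls[table.calls["variant_id"].isin(final)]
    wide = calls.pivot_table(index="sample", columns="variant_id", values="NV").fillna(0)
    mat = (wide >= 1).astype(int)
    mat = mat.reindex(index=table.tumour_samples, columns=final, fill_value=0)
    mat.loc[OUTGROUP_LABEL] = 0
    return mat


def filter_cascade(table: VariantTable, vafadj_threshold: float = 0.05) -> FilterResult:
    """Run the full cascade and assemble the audit trail."""
    audit: dict[str, str] = {}
    candidates = candidate_filter(table, audit=audit)
    retained = joint_filter(table, candidates, audit=audit)
    final, vafadj = vafadj_filter(table, retained, threshold=vafadj_threshold, audit=audit)
    rows = []
    for vid in table.variant_ids:
        reason = audit.get(vid)
        if reason is None:
            rows.append((vid, "passed", pd.NA))
        else:
            stage, rule = reason.split(":", 1)
            rows.append((vid, stage, rule))
    audit_df = pd.DataFrame(rows, columns=["variant_id", "stage", "first_failed_rule"])
    matrix = binarize(table, final) if final else pd.DataFrame()
    return FilterResult(
        candidates=candidates,
        retained=retained,
        final=final,
        audit=audit_df,
        vafadj=vafadj,
        matrix=matrix,
    )


def write_variant_tsv(table: VariantTable, path: str | Path) -> None:
    cols = list(REQUIRED_COLUMNS)
    table.calls[cols].to_csv(path, sep="\t", index=False)


def read_variant_tsv(
    path: str | Path, normal: str, purity: dict[str, float] | None = None
) -> VariantTable:
    """Read the flat TSV dialect (columns chrom,pos,ref,alt,sample,NR,NV,GT,GQ,flag)."""
    calls = pd.read_csv(path, sep="\t", dtype={"chrom": str, "GT": str, "flag": str})
    return VariantTable(calls=calls, normal=normal, purity=purity or {})
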