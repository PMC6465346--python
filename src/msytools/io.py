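"""Readers and writers for the plain-text formats the pipeline speaks.

BED intervals are 0-based half-open; VCF positions are 1-based. The
conversion happens exactly once, at this boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .coverage import (
    ClassifierConfig,
    ContigSummary,
    SampleProfile,
    WindowClass,
    WindowRecord,
)
from .phylogeny import ANCESTRAL, DERIVED, MISSING, CladeTree, HaploMatrix, LiftoverResult
from .rates import PedigreeLink
from .variants import (
    ALLELE_ALT,
    ALLELE_HET,
    ALLELE_MISSING,
    ALLELE_REF,
    FilterParams,
    FilterReport,
    GenotypeCall,
    VariantRecord,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coverage tables and profiles


def read_coverage_table(path: str | Path) -> tuple[list[WindowRecord], list[str]]:
    """TSV with columns contig, start, end and one coverage column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = ["contig", "start", "end"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: first columns must be {required}")
    samples = list(df.columns[3:])
    if not samples:
        raise ValueError(f"{path}: no sample columns")
    # contigs must be grouped and starts sorted within each contig
    contigs = list(df["contig"])
    starts = list(df["start"])
    seen_done: set[str] = set()
    prev_contig = None
    for i in range(len(contigs)):
        if contigs[i] != prev_contig:
            if contigs[i] in seen_done:
                raise ValueError(
                    f"{path}: windows not sorted at line {i + 2} "
                    f"(contig {contigs[i]} reappears)"
                )
            if prev_contig is not None:
                seen_done.add(prev_contig)
            prev_contig = contigs[i]
        elif starts[i] < starts[i - 1]:
            raise ValueError(f"{path}: windows not sorted at line {i + 2}")
    if len(set(zip(df["contig"], df["start"], df["end"]))) != len(df):
        raise ValueError(f"{path}: duplicate windows")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                WindowRecord(
                    row.contig,
                    int(row.start),
                    int(row.end),
                    {s: float(getattr(row, s)) for s in samples},
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i + 2}: {exc}") from exc
    return records, samples


def write_coverage_table(
    path: str | Path, windows: Sequence[WindowRecord], samples: Sequence[str]
) -> None:
    rows = [
        {"contig": w.contig, "start": w.start, "end": w.end,
         **{s: w.y[s] for s in samples}}
        for w in windows
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[SampleProfile]:
    """TSV with columns sample_id, sex, c, b (b empty or '.' for males)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str})
    out = []
    for row in df.itertuples(index=False):
        b = getattr(row, "b", None)
        if b is not None and (pd.isna(b) or b == "."):
            b = None
        out.append(SampleProfile(row.sample_id, row.sex, float(row.c),
                                 None if b is None else float(b)))
    return out


def write_profiles(path: str | Path, profiles: Sequence[SampleProfile]) -> None:
    rows = [
        {"sample_id": p.sample_id, "sex": p.sex, "c": p.c,
         "b": "." if p.b is None else p.b}
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: expected >= 3 BED columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_classes_bed(path: str | Path, classes: Sequence[WindowClass]) -> None:
    """BED6-minus-strand: name = class label, score = round(1000 * posterior)."""
    with open(path, "w") as fh:
        for wc in classes:
            w = wc.window
            score = int(round(1000 * wc.fit.posterior_msy))
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\t{wc.label}\t{score}\n")


def write_contig_summary(
    path: str | Path, summaries: Mapping[str, ContigSummary]
) -> None:
    rows = [
        {"contig": s.contig, "length": s.length, "n_windows": s.n_windows,
         "scY_bp": s.scY_bp, "mcY_bp": s.mcY_bp, "nonMSY_bp": s.nonMSY_bp,
         "y_content": round(s.y_content, 4), "kept": s.kept}
        for s in summaries.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF


def _classify_gt(alleles: list[int]) -> str:
    observed = [a for a in alleles if a >= 0]
    if not observed:
        return ALLELE_MISSING
    if all(a == 0 for a in observed):
        return ALLELE_REF
    if all(a == observed[0] for a in observed):
        return ALLELE_ALT
    return ALLELE_HET


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str], str]:
    """Parse a VCF into typed records.

    Returns (records, sample ids, raw header). Both haploid ("1") and
    diploid ("0/1") genotype dialects are accepted; the phased flag is read
    from the textual GT separator because htslib reports every haploid call
    as phased.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    header = vcf.raw_header
    records: list[VariantRecord] = []
    for rec in vcf:
        raw = str(rec).rstrip("\n")
        fields = raw.split("\t")
        fmt_keys = fields[8].split(":")
        if "GT" not in fmt_keys:
            raise ValueError(f"{path}: record at {rec.CHROM}:{rec.POS} lacks GT")
        gt_pos = fmt_keys.index("GT")
        try:
            depths = rec.format("DP")
        except KeyError:
            depths = None
        try:
            quals = rec.format("GQ")
        except KeyError:
            quals = None
        if depths is None or quals is None:
            missing = "DP" if depths is None else "GQ"
            raise ValueError(
                f"{path}: record at {rec.CHROM}:{rec.POS} lacks FORMAT field {missing}"
            )
        calls = []
        for i, sid in enumerate(samples):
            gt_str = fields[9 + i].split(":")[gt_pos]
            phased = "|" in gt_str
            alleles = [a for a in rec.genotypes[i][:-1] if isinstance(a, int)]
            dp = int(depths[i][0]) if depths[i][0] >= 0 else 0
            gq = int(quals[i][0]) if quals[i][0] >= 0 else 0
            calls.append(GenotypeCall(sid, _classify_gt(alleles), dp, gq, phased))
        records.append(
            VariantRecord(
                contig=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_alleles=list(rec.ALT),
                calls=calls,
                variant_id=rec.ID,
                raw_line=raw,
            )
        )
    return records, samples, header


_FILTER_DEFS = [
    '##FILTER=<ID=not_scY,Description="Outside single-copy Y windows">',
    '##FILTER=<ID=phased,Description="Phased genotype separator present">',
    '##FILTER=<ID=multiallelic,Description="More than one alternate allele">',
    '##FILTER=<ID=reference_error,Description="Alternate allele fixed in all samples">',
    '##FILTER=<ID=low_quality,Description="No call with sufficient depth and GQ">',
    '##FILTER=<ID=high_missingness,Description="Too many het or missing calls">',
]


def write_vcf(
    path: str | Path, records: Sequence[VariantRecord], header: str
) -> None:
    """Write records with the FILTER column annotated per filter stage."""
    lines = header.rstrip("\n").split("\n")
    out_header = lines[:-1] + _FILTER_DEFS + [lines[-1]]
    with open(path, "w") as fh:
        fh.write("\n".join(out_header) + "\n")
        for rec in records:
            if rec.raw_line is None:
                raise ValueError("record has no raw line to write")
            fields = rec.raw_line.split("\t")
            fields[6] = rec.filter_status
            fh.write("\t".join(fields) + "\n")


def write_filter_report(path: str | Path, report: FilterReport) -> None:
    rows = [{"stage": "input", "count": report.n_input}]
    rows += [{"stage": s, "count": n} for s, n in report.removed.items()]
    rows.append({"stage": "kept", "count": report.n_kept})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# haplotype matrices


_STATE_TO_CHAR = {ANCESTRAL: "0", DERIVED: "1", MISSING: "."}
_CHAR_TO_STATE = {v: k for k, v in _STATE_TO_CHAR.items()}


def read_matrix_tsv(path: str | Path, outgroup_id: str | None = None) -> HaploMatrix:
    """Rows = samples, columns = variant ids, cells in {0, 1, .}."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    samples = [str(s) for s in df.index]
    sites = [str(c) for c in df.columns]
    states = np.empty((len(samples), len(sites)), dtype=np.int8)
    for i in range(len(samples)):
        for j in range(len(sites)):
            cell = df.iat[i, j]
            try:
                states[i, j] = _CHAR_TO_STATE[cell]
            except KeyError:
                raise ValueError(
                    f"{path}: bad cell {cell!r} for {samples[i]}/{sites[j]}"
                ) from None
    return HaploMatrix(samples, sites, states, outgroup_id)


def write_matrix_tsv(path: str | Path, matrix: HaploMatrix) -> None:
    df = pd.DataFrame(
        [[_STATE_TO_CHAR[int(v)] for v in row] for row in matrix.states],
        index=matrix.samples,
        columns=matrix.sites,
    )
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# trees, liftover, pedigrees, FASTA


def write_newick(path: str | Path, tree: CladeTree) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_branch_table(path: str | Path, tree: CladeTree) -> None:
    rows = [
        {"branch": label, "n_mutations": len(muts),
         "variant_ids": ",".join(muts)}
        for label, muts in tree.branch_mutations().items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_liftover_table(
    path: str | Path, results: Sequence[LiftoverResult]
) -> None:
    rows = [
        {"variant_id": r.variant_id, "status": r.status,
         "target_contig": r.target_contig or ".",
         "target_pos": r.target_pos if r.target_pos is not None else ".",
         "strand": r.strand or "."}
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> list[PedigreeLink]:
    df = pd.read_csv(path, sep="\t", dtype={"father_id": str, "son_id": str})
    return [
        PedigreeLink(r.father_id, r.son_id, int(r.father_birth), int(r.son_birth))
        for r in df.itertuples(index=False)
    ]


def write_pedigree(path: str | Path, links: Sequence[PedigreeLink]) -> None:
    rows = [
        {"father_id": ln.father_id, "son_id": ln.son_id,
         "father_birth": ln.father_birth, "son_birth": ln.son_birth}
        for ln in links
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# config


def load_classifier_config(path: str | Path | None) -> ClassifierConfig:
    if path is None:
        return ClassifierConfig()
    with open(path) as fh:
        return ClassifierConfig(**json.load(fh))


def load_filter_params(path: str | Path | None) -> FilterParams:
    if path is None:
        return FilterParams()
    with open(path) as fh:
        return FilterParams(**json.load(fh))
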