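"""lncRNA identification cascade and transcript characteristic summaries.

Candidate transcripts pass a structural filter (minimum length, exon count
and read support, each a strict less-than rejection) and survivors are
split by coding potential: a transcript with CNCI < 0 **and** CPC < −1 is
called a lncRNA, anything else a protein-coding mRNA. Rejections are
attributed to the first failing rule in the order length, exons, reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "classify_transcripts",
    "summarize_characteristics",
    "read_score_table",
]

_SCORE_COLS = ("length", "exon_count", "read_support", "cnci", "cpc")


@dataclass
class FilterReport:
    total: int = 0
    rejected_length: int = 0
    rejected_exons: int = 0
    rejected_reads: int = 0
    rejected_missing_score: int = 0
    lncrna: int = 0
    mrna: int = 0
    #: transcript ids rejected for missing scores
    missing_score_ids: list[str] = field(default_factory=list)

    @property
    def rejected(self) -> int:
        return (
            self.rejected_length
            + self.rejected_exons
            + self.rejected_reads
            + self.rejected_missing_score
        )

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "rejected": self.rejected,
            "rejected_length": self.rejected_length,
            "rejected_exons": self.rejected_exons,
            "rejected_reads": self.rejected_reads,
            "rejected_missing_score": self.rejected_missing_score,
            "lncRNA": self.lncrna,
            "mRNA": self.mrna,
            "missing_score_ids": list(self.missing_score_ids),
        }


def classify_transcripts(
    records: pd.DataFrame,
    min_length: float = 200,
    min_exons: int = 1,
    min_reads: int = 3,
    cnci_max: float = 0.0,
    cpc_max: float = -1.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Assign a biotype to every candidate transcript.

    ``records`` needs columns length, exon_count, read_support, cnci, cpc
    (plus any identifier columns, carried through). A record is rejected
    iff length < min_length OR exon_count < min_exons OR read_support <
    min_reads (boundary values are retained); among survivors, lncRNA iff
    cnci < cnci_max AND cpc < cpc_max, else mRNA. Records with a missing
    score are rejected and listed in the report. The default min_exons=1
    keeps every exon count, mirroring the cascade's literal "fewer than 1
    exon" rule; raise it to 2 for the stricter common practice.

    Returns (copy of records with a ``biotype`` column, FilterReport).
    """
    missing = [c for c in _SCORE_COLS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    out = records.copy()
    report = FilterReport(total=len(out))
    if len(out) == 0:
        out["biotype"] = pd.Series(dtype=object)
        return out, report

    has_scores = out[list(_SCORE_COLS)].notna().all(axis=1).to_numpy()
    length = out["length"].to_numpy(dtype=float)
    exons = out["exon_count"].to_numpy(dtype=float)
    reads = out["read_support"].to_numpy(dtype=float)
    cnci = out["cnci"].to_numpy(dtype=float)
    cpc = out["cpc"].to_numpy(dtype=float)

    biotype = np.empty(len(out), dtype=object)
    # first-failing-rule attribution: length, exons, reads, then scores
    fail_len = has_scores & (length < min_length)
    fail_ex = has_scores & ~fail_len & (exons < min_exons)
    fail_rd = has_scores & ~fail_len & ~fail_ex & (reads < min_reads)
    survivors = has_scores & ~fail_len & ~fail_ex & ~fail_rd
    is_lnc = survivors & (cnci < cnci_max) & (cpc < cpc_max)
    is_mrna = survivors & ~is_lnc

    biotype[~has_scores] = "rejected"
    biotype[fail_len | fail_ex | fail_rd] = "rejected"
    biotype[is_lnc] = "lncRNA"
    biotype[is_mrna] = "mRNA"
    out["biotype"] = biotype

    report.rejected_missing_score = int((~has_scores).sum())
    if report.rejected_missing_score and "transcript_id" in out.columns:
        report.missing_score_ids = out.loc[
            ~has_scores, "transcript_id"
        ].tolist()
    report.rejected_length = int(fail_len.sum())
    report.rejected_exons = int(fail_ex.sum())
    report.rejected_reads = int(fail_rd.sum())
    report.lncrna = int(is_lnc.sum())
    report.mrna = int(is_mrna.sum())
    return out, report


_LENGTH_BINS = (200, 1000, 3000)
_LENGTH_LABELS = ("200-1000", "1000-3000", ">3000")


def summarize_characteristics(records: pd.DataFrame) -> dict[str, dict]:
    """Per-biotype length and exon-count summaries.

    For each biotype present (lncRNA / mRNA): mean length, fraction of
    transcripts per length bin ([200, 1000], (1000, 3000], > 3000 nt; any
    transcript below 200 nt is counted into the first bin), the exon-count
    distribution, and the fraction of transcripts with ≤ 2 exons.
    """
    summary: dict[str, dict] = {}
    for biotype, grp in records.groupby("biotype"):
        if biotype not in ("lncRNA", "mRNA"):
            continue
        lengths = grp["length"].to_numpy(dtype=float)
        exons = grp["exon_count"].to_numpy(dtype=int)
        bins = np.array(
            [
                (lengths <= _LENGTH_BINS[1]).sum(),
                ((lengths > _LENGTH_BINS[1]) & (lengths <= _LENGTH_BINS[2])).sum(),
                (lengths > _LENGTH_BINS[2]).sum(),
            ],
            dtype=float,
        )
        exon_counts = pd.Series(exons).value_counts().sort_index()
        summary[biotype] = {
            "n": len(grp),
            "mean_length": float(lengths.mean()),
            "length_bin_fractions": dict(
                zip(_LENGTH_LABELS, (bins / bins.sum()).tolist())
            ),
            "exon_distribution": {
                int(k): int(v) for k, v in exon_counts.items()
            },
            "fraction_le2_exons": float((exons <= 2).mean()),
        }
    return summary


def read_score_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-transcript score TSV, optionally remapping column names.

    ``column_map`` maps the file's column names onto the expected ones
    (transcript_id, exon_count, read_support, cnci, cpc), adapting score
    tables produced by arbitrary coding-potential tools.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    required = {"transcript_id", "exon_count", "read_support", "cnci", "cpc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    return df
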