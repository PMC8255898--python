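"""Reading and writing transcript annotations as GTF.

Coordinates are 1-based inclusive on disk (GTF convention). The in-memory
annotation table keeps the same convention; interval arithmetic elsewhere
converts to 0-based half-open internally. Each transcript carries
``transcript_id``, ``gene_id`` and ``biotype`` attributes plus one row per
exon. Parsing goes through gffutils (in-memory database); writing is plain
line formatting.
"""

from __future__ import annotations

import gffutils
import pandas as pd

__all__ = ["write_gtf", "read_gtf"]

_SOURCE = "growthlnc"


def _attr_string(transcript_id: str, gene_id: str, biotype: str) -> str:
    return (
        f'gene_id "{gene_id}"; transcript_id "{transcript_id}"; '
        f'biotype "{biotype}";'
    )


def write_gtf(transcripts: pd.DataFrame, path) -> None:
    """Write an annotation table to GTF.

    Expects columns transcript_id, gene_id, chrom, strand, start, end,
    biotype, and optionally exon_starts / exon_ends (lists of 1-based
    inclusive coordinates). Without exon columns each transcript is
    written as a single exon spanning the transcript.
    """
    has_exons = {"exon_starts", "exon_ends"} <= set(transcripts.columns)
    with open(path, "w") as fh:
        for row in transcripts.itertuples(index=False):
            attrs = _attr_string(row.transcript_id, row.gene_id, row.biotype)
            fh.write(
                f"{row.chrom}\t{_SOURCE}\ttranscript\t{int(row.start)}\t"
                f"{int(row.end)}\t.\t{row.strand}\t.\t{attrs}\n"
            )
            if has_exons:
                starts, ends = row.exon_starts, row.exon_ends
            else:
                starts, ends = [row.start], [row.end]
            for s, e in zip(starts, ends):
                fh.write(
                    f"{row.chrom}\t{_SOURCE}\texon\t{int(s)}\t{int(e)}\t.\t"
                    f"{row.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> pd.DataFrame:
    """Read a GTF into an annotation table (one row per transcript).

    Returns columns transcript_id, gene_id, chrom, strand, start, end,
    length (sum of exon lengths, nt), exon_count, biotype, exon_starts,
    exon_ends. Length and exon count are reconstructed from exon features.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        exons.setdefault(tid, []).append((ex.start, ex.end))
    rows = []
    for tr in db.features_of_type("transcript"):
        tid = tr.attributes["transcript_id"][0]
        ex = sorted(exons.get(tid, [(tr.start, tr.end)]))
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": tr.attributes["gene_id"][0],
                "chrom": tr.seqid,
                "strand": tr.strand,
                "start": tr.start,
                "end": tr.end,
                "length": sum(e - s + 1 for s, e in ex),
                "exon_count": len(ex),
                "biotype": tr.attributes.get("biotype", ["candidate"])[0],
                "exon_starts": [s for s, _ in ex],
                "exon_ends": [e for _, e in ex],
            }
        )
    return pd.DataFrame(rows).sort_values("transcript_id", ignore_index=True)
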