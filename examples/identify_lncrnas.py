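"""Run the lncRNA identification cascade on a simulated annotation.

Builds a toy genome with known lncRNA/mRNA ground truth, classifies each
candidate transcript by transcript length (>= 200 nt), read support
(>= 3 reads) and coding-potential scores (CNCI < 0 and CPC < -1 for a
lncRNA), and summarizes the structural differences between the two
biotypes.
"""

import json

from growthlnc import (
    classify_transcripts,
    simulate_annotation,
    summarize_characteristics,
)

annotation, scores, _ = simulate_annotation(seed=1)
candidates = annotation.drop(columns=["biotype", "exon_count"]).merge(
    scores, on="transcript_id"
)
classified, report = classify_transcripts(candidates)
print("filter report:", json.dumps(report.as_dict(), indent=2))

summary = summarize_characteristics(classified)
for biotype, s in summary.items():
    print(
        f"{biotype}: n={s['n']}, mean length {s['mean_length']:.0f} nt, "
        f"{100 * s['fraction_le2_exons']:.1f}% with <= 2 exons"
    )
truth_lnc = (annotation["biotype"] == "lncRNA").sum()
print(
    f"\n{report.lncrna} transcripts called lncRNA vs {truth_lnc} planted — "
    "the cascade recovers the planted biotypes up to score-boundary "
    "crossers, and lncRNAs show the expected 1-2 exon skew."
)
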