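"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of their parameters and an explicit
seed:

* :func:`simulate_growth_cohort` — longitudinal body weights for a cohort
  weighed repeatedly from birth, emulating a 126-animal herd measured at
  18 time points between birth and 400 d.
* :func:`simulate_annotation` — a toy multi-chromosome genome with mRNA and
  lncRNA loci, laid out so that a chosen number of lncRNAs sit within the
  100-kb cis window of a designated mRNA and all remaining lncRNAs are
  more than one window away from every mRNA. Coding-potential scores,
  exon counts and read support are drawn so lncRNAs skew to 1–2 exons and
  strongly negative CNCI/CPC, mRNAs to ≥3 exons and positive scores.
* :func:`simulate_expression` — a two-condition (3 vs 3 replicate by
  default) negative-binomial count matrix with planted fold changes and,
  for planted cis pairs, a shared per-sample latent factor that makes the
  partners' expression strongly correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthModelParams, evaluate_model

__all__ = [
    "SimulationTruth",
    "DEFAULT_AGES",
    "simulate_growth_cohort",
    "simulate_annotation",
    "simulate_expression",
]

#: 18 weighing ages spanning birth to 400 d, evenly spaced.
DEFAULT_AGES = tuple(np.linspace(0.0, 400.0, 18))

# genomic layout constants for simulate_annotation
_SLOT_SPACING = 300_000  # bp between gene slots; >> cis window
_MAX_SPAN = 20_000  # cap on genomic span of one gene
_CIS_WINDOW = 100_000  # bp; planted pairs fall inside, others far outside
_MAX_PLANTED_GAP = 90_000  # planted pair gap drawn in [0, this]

#: lognormal sigma of the shared latent factor given to planted cis pairs
LATENT_SIGMA = 0.3
#: minimum library share of a planted cis-pair gene, so the latent signal
#: is far above Poisson counting noise and the pair correlation observable
_CIS_MIN_SHARE = 0.002


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated data set."""

    growth_params: GrowthModelParams | None = None
    #: gene id -> planted log2 fold change (condition A over condition B)
    de_genes: dict[str, float] = field(default_factory=dict)
    #: (lncRNA gene id, mRNA gene id, genomic gap in bp)
    cis_pairs: list[tuple[str, str, int]] = field(default_factory=list)


def simulate_growth_cohort(
    params: GrowthModelParams,
    n_animals: int = 126,
    ages=DEFAULT_AGES,
    noise_sd: float = 2.0,
    animal_cv: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Longitudinal weight records for a cohort following one growth model.

    Each animal gets its own asymptote ``A_i = A · f_i`` with
    ``f_i ~ Normal(1, animal_cv)`` (truncated at 0.5), plus independent
    Gaussian measurement noise of ``noise_sd`` kg on every weighing;
    weights are floored at 0.1 kg. The default 10% between-animal CV
    matches the dispersion typical of slaughter weights in an unselected
    herd.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0 or (ages < 0).any():
        raise ValueError("ages must be non-empty and non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if animal_cv < 0:
        raise ValueError("animal_cv must be non-negative")
    rng = np.random.default_rng(seed)
    factors = np.maximum(rng.normal(1.0, animal_cv, n_animals), 0.5)
    rows = []
    for i in range(n_animals):
        p_i = GrowthModelParams(
            params.model, params.A * factors[i], params.B, params.k
        )
        w = np.asarray(evaluate_model(p_i, ages))
        w = w + rng.normal(0.0, noise_sd, ages.size)
        w = np.maximum(w, 0.1)
        for a, wt in zip(ages, w):
            rows.append((f"animal_{i + 1:03d}", float(a), float(wt)))
    records = pd.DataFrame(rows, columns=["animal_id", "age_days", "weight_kg"])
    return records, SimulationTruth(growth_params=params)


def _draw_transcript(rng: np.random.Generator, kind: str) -> tuple[int, int]:
    """(length nt, exon count) for one transcript of the given biotype."""
    if kind == "lncRNA":
        length = int(
            rng.uniform(200, 1000) if rng.random() < 0.7
            else rng.uniform(1000, 3000)
        )
        exons = int(rng.choice([1, 2, 3, 4], p=[0.55, 0.30, 0.10, 0.05]))
    else:
        length = int(
            rng.uniform(600, 3000) if rng.random() < 0.85
            else rng.uniform(3000, 6000)
        )
        exons = int(
            rng.choice(np.arange(1, 11), p=[0.03, 0.07] + [0.9 / 8] * 8)
        )
    return length, exons


def _exon_layout(
    rng: np.random.Generator, start: int, length: int, exons: int
) -> tuple[list[int], list[int], int]:
    """Exon coordinates (1-based inclusive) and gene end for one transcript."""
    sizes = np.full(exons, length // exons, dtype=int)
    sizes[: length % exons] += 1
    if exons > 1:
        total_intron = int(rng.integers(200, 2001)) * (exons - 1)
        total_intron = min(total_intron, _MAX_SPAN - length)
        introns = np.full(exons - 1, total_intron // (exons - 1), dtype=int)
        introns[: total_intron % (exons - 1)] += 1
    else:
        introns = np.empty(0, dtype=int)
    starts, ends = [], []
    pos = start
    for i in range(exons):
        starts.append(pos)
        ends.append(pos + int(sizes[i]) - 1)
        if i < exons - 1:
            pos = ends[-1] + int(introns[i]) + 1
    return starts, ends, ends[-1]


def simulate_annotation(
    n_chromosomes: int = 3,
    chrom_length: int = 16_000_000,
    n_mrna: int = 90,
    n_lnc: int = 60,
    planted_cis: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Toy genome annotation with a controlled cis-pair structure.

    Genes occupy slots spaced 300 kb apart, so any two genes in different
    slots are > 100 kb apart; exactly ``planted_cis`` lncRNAs are instead
    placed 0–90 kb downstream of a designated mRNA, making them the only
    distance-eligible lncRNA–mRNA pairs under a 100-kb window.

    Returns (transcript table, score table, truth). The score table carries
    per-transcript exon count, read support and CNCI/CPC coding-potential
    scores (lncRNAs centred at CNCI −5 / CPC −3; mRNAs at +5 / +2, so a
    small fraction of boundary crossers is expected).
    """
    if planted_cis > min(n_mrna, n_lnc):
        raise ValueError("planted_cis cannot exceed min(n_mrna, n_lnc)")
    rng = np.random.default_rng(seed)
    last_start = chrom_length - _MAX_SPAN - _MAX_PLANTED_GAP - _MAX_SPAN
    slots = [
        (f"chr{c + 1}", int(pos))
        for c in range(n_chromosomes)
        for pos in range(100_000, last_start + 1, _SLOT_SPACING)
    ]
    n_standalone = n_lnc - planted_cis
    if n_mrna + n_standalone > len(slots):
        raise ValueError(
            f"genome too short: {len(slots)} slots available for "
            f"{n_mrna + n_standalone} genes; increase chrom_length or "
            "n_chromosomes"
        )
    order = rng.permutation(len(slots))[: n_mrna + n_standalone]
    mrna_slots = [slots[i] for i in order[:n_mrna]]
    lnc_slots = [slots[i] for i in order[n_mrna:]]

    rows = []

    def add_gene(gid: str, kind: str, chrom: str, start: int) -> int:
        length, exons = _draw_transcript(rng, kind)
        ex_starts, ex_ends, end = _exon_layout(rng, start, length, exons)
        rows.append(
            {
                "transcript_id": f"{gid}.1",
                "gene_id": gid,
                "chrom": chrom,
                "strand": "+" if rng.random() < 0.5 else "-",
                "start": start,
                "end": end,
                "length": length,
                "exon_count": exons,
                "biotype": kind,
                "exon_starts": ex_starts,
                "exon_ends": ex_ends,
            }
        )
        return end

    mrna_ends = []
    for j, (chrom, pos) in enumerate(mrna_slots):
        end = add_gene(f"MRNA{j + 1:04d}", "mRNA", chrom, pos)
        mrna_ends.append((chrom, end))
    for j, (chrom, pos) in enumerate(lnc_slots):
        add_gene(f"LNC{j + 1:04d}", "lncRNA", chrom, pos)

    cis_pairs: list[tuple[str, str, int]] = []
    partners = rng.choice(n_mrna, size=planted_cis, replace=False)
    for j, mi in enumerate(sorted(partners)):
        chrom, m_end = mrna_ends[mi]
        gap = int(rng.integers(0, _MAX_PLANTED_GAP + 1))
        gid = f"LNC{n_standalone + j + 1:04d}"
        add_gene(gid, "lncRNA", chrom, m_end + gap + 1)
        cis_pairs.append((gid, f"MRNA{mi + 1:04d}", gap))

    transcripts = pd.DataFrame(rows).sort_values(
        "transcript_id", ignore_index=True
    )
    is_lnc = transcripts["biotype"] == "lncRNA"
    n = len(transcripts)
    scores = pd.DataFrame(
        {
            "transcript_id": transcripts["transcript_id"],
            "exon_count": transcripts["exon_count"],
            "read_support": rng.poisson(30, n) + 3,
            "cnci": np.where(
                is_lnc, rng.normal(-5, 2, n), rng.normal(5, 2, n)
            ),
            "cpc": np.where(
                is_lnc, rng.normal(-3, 1, n), rng.normal(2, 1, n)
            ),
        }
    )
    return transcripts, scores, SimulationTruth(cis_pairs=cis_pairs)


def simulate_expression(
    annotation: pd.DataFrame,
    n_de: int = 50,
    log2fc_range: tuple[float, float] = (1.5, 3.0),
    dispersion: float = 0.1,
    depth: int = 5_000_000,
    n_reps: int = 3,
    cis_pairs: list[tuple[str, str, int]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Two-condition count matrix with planted differential expression.

    Gene baselines are drawn log-normal(ln 50, 1) (capped at 1% of the
    library so no single gene dominates); each gene in each library gets a
    gamma biological-variability multiplier (mean 1, variance
    ``dispersion``), and exactly ``depth`` reads are then drawn
    multinomially from the library composition. Per-gene counts are thus
    marginally gamma-Poisson — negative binomial with variance μ + φμ² —
    while every column sum equals ``depth`` exactly. Planted DE genes
    split the fold change symmetrically between the two conditions.
    Partners of planted cis pairs share a per-sample lognormal latent
    factor (σ = 0.3) in place of independent gamma multipliers and are
    floored at 0.2% of the library, so their expression correlation across
    samples approaches 1; cis-pair genes are excluded from the DE draw to
    keep the two truths independent.

    Returns (counts genes × samples, sample sheet, truth).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    genes = annotation["gene_id"].drop_duplicates().tolist()
    if n_de > len(genes):
        raise ValueError("n_de cannot exceed the number of genes")
    rng = np.random.default_rng(seed)
    g = len(genes)
    base = rng.lognormal(np.log(50.0), 1.0, g)
    # cap any one gene at 1% of the library: with NB overdispersion plus
    # fold-change scaling, a dominant gene would make realised library
    # sizes swing far from the requested depth
    base = np.minimum(base, 0.01 * base.sum())
    mu = base / base.sum() * depth

    cis_pairs = list(cis_pairs or [])
    cis_genes = {gid for pair in cis_pairs for gid in pair[:2]}
    idx = {gid: i for i, gid in enumerate(genes)}
    for gid in cis_genes:
        mu[idx[gid]] = max(mu[idx[gid]], _CIS_MIN_SHARE * depth)

    candidates = [gid for gid in genes if gid not in cis_genes]
    de_ids = list(rng.choice(candidates, size=n_de, replace=False))
    lfc = rng.uniform(*log2fc_range, n_de) * rng.choice([1.0, -1.0], n_de)
    de_genes = {gid: float(f) for gid, f in zip(de_ids, lfc)}

    mean_a = mu.copy()
    mean_b = mu.copy()
    for gid, f in de_genes.items():
        mean_a[idx[gid]] = mu[idx[gid]] * 2 ** (f / 2.0)
        mean_b[idx[gid]] = mu[idx[gid]] * 2 ** (-f / 2.0)

    samples = [f"A_{r + 1}" for r in range(n_reps)] + [
        f"B_{r + 1}" for r in range(n_reps)
    ]
    conditions = ["A"] * n_reps + ["B"] * n_reps
    means = np.column_stack([mean_a] * n_reps + [mean_b] * n_reps)

    # biological variability: a gamma multiplier (mean 1, var = dispersion)
    # per gene per library; sequencing: multinomial sampling of exactly
    # `depth` reads from the library composition, so per-gene marginals are
    # gamma-Poisson (negative binomial, variance mu + dispersion*mu^2) and
    # every column sum equals the requested depth
    if dispersion > 0:
        mult = rng.gamma(1.0 / dispersion, dispersion, means.shape)
    else:
        mult = np.ones_like(means)
    # planted cis partners: one latent factor per sample shared by the pair
    for lnc_id, mrna_id, _ in cis_pairs:
        f_s = rng.lognormal(-(LATENT_SIGMA**2) / 2.0, LATENT_SIGMA, len(samples))
        mult[idx[lnc_id], :] = f_s
        mult[idx[mrna_id], :] = f_s
    weights = means * mult
    probs = weights / weights.sum(axis=0, keepdims=True)
    counts = np.column_stack(
        [rng.multinomial(depth, probs[:, s]) for s in range(len(samples))]
    ).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=samples)
    sheet = pd.DataFrame({"sample_id": samples, "condition": conditions})
    return counts_df, sheet, SimulationTruth(
        de_genes=de_genes, cis_pairs=cis_pairs
    )
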