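"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions of a convergent miRNA/gene
screen: a 2555-miRNA mimic screen with heavy-tailed planted effects, K
prediction algorithms with controllable per-pair call probability and
inter-algorithm agreement, planted "convergent" genes whose binder sets
are enriched for candidate miRNAs, an 832-gene siRNA hit list,
allele-specific planted seed sites in random 3'UTRs, paired pre/post
synaptic puncta clouds with a set connectivity fraction, and qPCR Ct
tables with a planted group fold change.

One integer seed drives everything: each generator derives its own
independent stream from (seed, fixed stream id), so outputs are
byte-identical across runs and independent across generators.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import PredictionCallSet
from .puncta import PunctaSet
from .seeds import Haplotype3UTR, MiRNASeq, _revcomp, compare_alleles

__all__ = [
    "PlantedGene",
    "SynthConfig",
    "gen_screen_scores",
    "gen_prediction_calls",
    "gen_sirna_hits",
    "gen_variant_utr",
    "gen_puncta_pair",
    "gen_ct_table",
    "gen_null_binder_sets",
    "default_demo_config",
    "write_dataset",
]

_STREAMS = {
    "screen": 1,
    "calls": 2,
    "plant": 3,
    "sirna": 4,
    "utr": 5,
    "puncta": 6,
    "ct": 7,
    "misc": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class PlantedGene:
    """A convergent gene planted into the prediction calls: its consensus
    binder set has exactly ``binder_count`` miRNAs, of which exactly
    ``candidate_overlap`` are candidate miRNAs."""

    gene_id: str
    binder_count: int
    candidate_overlap: int

    def __post_init__(self) -> None:
        if not 0 <= self.candidate_overlap <= self.binder_count:
            raise ValueError(
                f"{self.gene_id}: need 0 <= candidate_overlap <= binder_count"
            )


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale defaults: 2555 screened miRNAs, 18107 genes, 6
    prediction algorithms with a >=4-algorithm consensus, 832 siRNA hits."""

    n_mirna: int = 2555
    n_gene: int = 18107
    n_algorithms: int = 6
    base_call_prob: float = 0.02
    agreement: float = 0.75
    consensus_min: int = 4
    n_sirna_hits: int = 832
    planted_genes: tuple[PlantedGene, ...] = ()
    n_planted_top: int = 0
    n_planted_bottom: int = 0
    planted_shift: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna < 4 or self.n_gene < 1 or self.n_algorithms < 1:
            raise ValueError("counts must be positive (n_mirna >= 4)")
        for p in (self.base_call_prob, self.agreement):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 1 <= self.consensus_min <= self.n_algorithms:
            raise ValueError("consensus_min must be within the algorithm universe")
        if self.n_planted_top + self.n_planted_bottom > self.n_mirna:
            raise ValueError("more planted miRNAs than the universe holds")
        if self.n_sirna_hits > self.n_gene:
            raise ValueError("n_sirna_hits exceeds the gene universe")
        object.__setattr__(self, "planted_genes", tuple(self.planted_genes))
        for pg in self.planted_genes:
            if pg.binder_count > self.n_mirna:
                raise ValueError(f"{pg.gene_id}: binder_count exceeds n_mirna")

    @property
    def mirna_ids(self) -> list[str]:
        width = len(str(self.n_mirna))
        return [f"miR-{i:0{width}d}" for i in range(1, self.n_mirna + 1)]

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_gene))
        return [f"GENE{i:0{width}d}" for i in range(1, self.n_gene + 1)]

    @property
    def algorithm_ids(self) -> tuple[str, ...]:
        return tuple(f"alg{i}" for i in range(1, self.n_algorithms + 1))

    def planted_top_ids(self) -> list[str]:
        return self.mirna_ids[: self.n_planted_top]

    def planted_bottom_ids(self) -> list[str]:
        return self.mirna_ids[self.n_planted_top: self.n_planted_top + self.n_planted_bottom]


def gen_screen_scores(config: SynthConfig) -> pd.DataFrame:
    """Screen score table: standard-normal background plus planted shifts.

    The first ``n_planted_top`` miRNA ids get +``planted_shift`` SD, the
    next ``n_planted_bottom`` get the negative shift, so planted entities
    land in the corresponding score tails.
    """
    rng = _rng(config.rng_seed, "screen")
    scores = rng.standard_normal(config.n_mirna)
    scores[: config.n_planted_top] += config.planted_shift
    scores[config.n_planted_top: config.n_planted_top + config.n_planted_bottom] -= (
        config.planted_shift
    )
    return pd.DataFrame({"entity_id": config.mirna_ids, "score": scores})


def _planted_binders(
    config: SynthConfig,
    candidates: Sequence[str],
    noncandidate_exclude: Iterable[str] = (),
) -> dict[str, list[str]]:
    """Deterministic planted binder sets: per gene, exactly k candidates
    (the i-th gene is forced to include the (i mod n_cand)-th candidate so
    that >= n_cand planted genes jointly cover every candidate) plus
    b - k non-candidates, all sampled without replacement.
    ``noncandidate_exclude`` keeps chosen miRNAs out of the non-candidate
    pool (e.g. screen-selected miRNAs meant to stay inactive)."""
    rng = _rng(config.rng_seed, "plant")
    cand = sorted(set(candidates))
    noncand = sorted(set(config.mirna_ids) - set(cand) - set(noncandidate_exclude))
    out: dict[str, list[str]] = {}
    for i, pg in enumerate(config.planted_genes):
        k, b = pg.candidate_overlap, pg.binder_count
        if k > len(cand):
            raise ValueError(f"{pg.gene_id}: candidate_overlap {k} > |candidates| {len(cand)}")
        if b - k > len(noncand):
            raise ValueError(f"{pg.gene_id}: not enough non-candidate miRNAs")
        chosen: list[str] = []
        if k > 0:
            anchor = cand[i % len(cand)]
            rest = [m for m in cand if m != anchor]
            chosen = [anchor] + list(rng.choice(rest, size=k - 1, replace=False))
        chosen += list(rng.choice(noncand, size=b - k, replace=False))
        out[pg.gene_id] = sorted(chosen)
    return out


def gen_prediction_calls(
    config: SynthConfig,
    candidates: Iterable[str] = (),
    noncandidate_exclude: Iterable[str] = (),
) -> PredictionCallSet:
    """Multi-algorithm call triples with planted consensus structure.

    Planted genes receive exactly their specified consensus binder sets:
    each planted binder is called by consensus_min + Binomial(K -
    consensus_min, agreement) algorithms, so it always clears the
    consensus threshold.  Background calls are independent Bernoulli at
    ``base_call_prob`` per (miRNA, gene, algorithm) over the non-planted
    genes only, which keeps the planted counts exact.
    """
    candidates = sorted(set(candidates))
    unknown = set(candidates) - set(config.mirna_ids)
    if unknown:
        raise ValueError(f"candidates outside the miRNA universe: {sorted(unknown)[:5]}")
    rng = _rng(config.rng_seed, "calls")
    K = config.n_algorithms
    algs = np.array(config.algorithm_ids)

    mirna_col: list[str] = []
    gene_col: list[str] = []
    alg_col: list[str] = []

    for gene_id, binders in _planted_binders(
        config, candidates, noncandidate_exclude
    ).items():
        for m in binders:
            extra = rng.binomial(K - config.consensus_min, config.agreement)
            called = rng.choice(K, size=config.consensus_min + extra, replace=False)
            for a in sorted(called):
                mirna_col.append(m)
                gene_col.append(gene_id)
                alg_col.append(algs[a])

    planted_ids = {pg.gene_id for pg in config.planted_genes}
    bg_genes = [g for g in config.gene_ids if g not in planted_ids]
    if bg_genes and config.base_call_prob > 0:
        n_pairs = len(bg_genes) * config.n_mirna
        mirna_arr = np.array(config.mirna_ids)
        gene_arr = np.array(bg_genes)
        chunk = 1 << 22
        for a in range(K):
            for start in range(0, n_pairs, chunk):
                stop = min(start + chunk, n_pairs)
                hit = np.flatnonzero(
                    rng.random(stop - start) < config.base_call_prob
                ) + start
                if hit.size:
                    mirna_col.extend(mirna_arr[hit % config.n_mirna])
                    gene_col.extend(gene_arr[hit // config.n_mirna])
                    alg_col.extend([algs[a]] * hit.size)

    calls = pd.DataFrame(
        {"mirna_id": mirna_col, "gene_id": gene_col, "algorithm_id": alg_col}
    ).sort_values(["gene_id", "mirna_id", "algorithm_id"], kind="mergesort").reset_index(drop=True)
    return PredictionCallSet(calls=calls, algorithms=config.algorithm_ids)


def gen_sirna_hits(config: SynthConfig) -> list[str]:
    """siRNA-screen hit gene list; every planted convergent gene is a hit."""
    rng = _rng(config.rng_seed, "sirna")
    planted = [pg.gene_id for pg in config.planted_genes]
    if len(planted) > config.n_sirna_hits:
        raise ValueError("more planted genes than siRNA hits")
    pool = [g for g in config.gene_ids if g not in set(planted)]
    extra = list(rng.choice(pool, size=config.n_sirna_hits - len(planted), replace=False))
    return sorted(planted + extra)


def gen_variant_utr(
    length: int,
    variant_pos: int,
    mirna: MiRNASeq,
    planted_allele: str = "alt",
    rng_seed: int = 0,
    gene_id: str = "SYNUTR",
) -> Haplotype3UTR:
    """Random 3'UTR haplotype pair with an optionally planted 8mer site.

    ``planted_allele``:

    * ``"alt"``  — the alt allele carries a canonical 8mer for ``mirna``
      whose seed core spans ``variant_pos``; the ref allele has no site
      for that miRNA at that locus (the risk-allele-gains-a-site case);
    * ``"ref"``  — the mirror case;
    * ``"both"`` — an 8mer away from the variant, present on both alleles;
    * ``"none"`` — no planting, the alleles just differ at ``variant_pos``.

    Raises ValueError when the variant sits too close to the UTR edge for
    a spanning site to exist, i.e. the site cannot be planted without a
    second sequence difference.
    """
    if planted_allele not in ("ref", "alt", "both", "none"):
        raise ValueError("planted_allele must be one of ref/alt/both/none")
    if not 1 <= variant_pos <= length:
        raise ValueError("variant_pos outside the UTR")
    if length < 12:
        raise ValueError("UTR too short")
    rng = _rng(rng_seed, "utr")
    bases = np.array(list("ACGU"))
    site8 = _revcomp(mirna.sequence[1:8]) + "A"
    v = variant_pos - 1

    for _ in range(100):
        seq = rng.choice(bases, size=length)
        if planted_allele in ("ref", "alt"):
            # seed core occupies window offsets 1..6; the variant must hit it
            offsets = [o for o in range(1, 7) if v - o >= 0 and v - o + 8 <= length]
            if not offsets:
                raise ValueError(
                    "variant_pos too close to the UTR edge: a seed-core-spanning "
                    "site cannot be planted without a second sequence difference"
                )
            w = v - int(rng.choice(offsets))
            seq[w: w + 8] = list(site8)
            carrier = "".join(seq)
            other_arr = seq.copy()
            other_arr[v] = rng.choice([b for b in "ACGU" if b != carrier[v]])
            other = "".join(other_arr)
            ref_seq, alt_seq = (carrier, other) if planted_allele == "ref" else (other, carrier)
        else:
            if planted_allele == "both":
                starts = [
                    w for w in range(0, length - 7)
                    if not (w <= v <= w + 7)
                ]
                if not starts:
                    raise ValueError("no room to plant a site away from the variant")
                w = int(rng.choice(starts))
                seq[w: w + 8] = list(site8)
            ref_seq = "".join(seq)
            alt_arr = seq.copy()
            alt_arr[v] = rng.choice([b for b in "ACGU" if b != ref_seq[v]])
            alt_seq = "".join(alt_arr)

        hap = Haplotype3UTR(
            gene_id=gene_id,
            ref_seq=ref_seq,
            alt_seq=alt_seq,
            variant_pos=variant_pos,
            ref_allele=ref_seq[v],
            alt_allele=alt_seq[v],
        )
        if _planting_ok(hap, mirna, planted_allele):
            return hap
    raise RuntimeError("could not generate a clean planted haplotype in 100 attempts")


def _planting_ok(hap: Haplotype3UTR, mirna: MiRNASeq, planted_allele: str) -> bool:
    # reject draws where the random background muddies the planted truth
    cmp = compare_alleles(hap, [mirna])
    if planted_allele == "alt":
        return (
            any(h.site_type == "8mer" for h in cmp.variant_created)
            and not cmp.variant_destroyed
        )
    if planted_allele == "ref":
        return (
            any(h.site_type == "8mer" for h in cmp.variant_destroyed)
            and not cmp.variant_created
        )
    if planted_allele == "both":
        return not cmp.variant_created and not cmp.variant_destroyed and any(
            h.site_type == "8mer" and h.allele_presence == "both" for h in cmp.hits
        )
    return True  # "none": no guarantee beyond the single-position difference


def gen_puncta_pair(
    n_pre: int,
    connected_fraction: float,
    jitter_sd: float = 0.1,
    box: tuple[float, float, float] = (50.0, 50.0, 10.0),
    n_distractor_post: int = 0,
    rng_seed: int = 0,
) -> tuple[PunctaSet, PunctaSet]:
    """Paired pre/post puncta clouds with a planted connectivity fraction.

    round(connected_fraction * n_pre) presynaptic puncta receive a partner
    postsynaptic punctum at an isotropic Gaussian offset (sd = jitter_sd
    per axis, µm); distractor posts are uniform in the box.  Warns when
    the box is crowded enough that nearest-neighbour spacing approaches
    the 1 µm assignment scale.
    """
    if not 0.0 <= connected_fraction <= 1.0:
        raise ValueError("connected_fraction must lie in [0, 1]")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if n_pre < 1:
        raise ValueError("n_pre must be >= 1")
    rng = _rng(rng_seed, "puncta")
    box_arr = np.asarray(box, dtype=float)
    volume = float(np.prod(box_arr))
    spacing = (volume / max(n_pre + n_distractor_post, 1)) ** (1.0 / 3.0)
    if spacing < 2.0:
        warnings.warn(
            f"expected nearest-neighbour spacing ~{spacing:.2f} µm is close to "
            "the 1 µm assignment threshold; connectivity readout may be inflated",
            stacklevel=2,
        )

    pre_xyz = rng.random((n_pre, 3)) * box_arr
    n_conn = int(round(connected_fraction * n_pre))
    partner = pre_xyz[:n_conn] + rng.normal(0.0, jitter_sd, size=(n_conn, 3))
    distract = rng.random((n_distractor_post, 3)) * box_arr
    post_xyz = np.vstack([partner, distract]) if (n_conn + n_distractor_post) else np.empty((0, 3))

    wid = max(4, len(str(max(n_pre, len(post_xyz)))))
    pre = PunctaSet(
        channel="pre",
        ids=[f"pre-{i:0{wid}d}" for i in range(1, n_pre + 1)],
        coords=pre_xyz,
    )
    post = PunctaSet(
        channel="post",
        ids=[f"post-{i:0{wid}d}" for i in range(1, len(post_xyz) + 1)],
        coords=post_xyz,
    )
    return pre, post


def gen_ct_table(
    n_per_group: int = 30,
    group_log2_fold: float = 1.0,
    noise_sd: float = 0.2,
    rng_seed: int = 0,
    target: str = "miR-4504",
    normalizer: str = "RNU48",
    reference_group: str = "CTL",
    case_group: str = "AD",
    base_target_ct: float = 25.0,
    base_normalizer_ct: float = 20.0,
) -> pd.DataFrame:
    """Two-group wide Ct table with a planted log2 fold change.

    Case-group target Ct is shifted by -group_log2_fold cycles (one cycle
    earlier = twice the template); the normalizer is unshifted.  Gaussian
    noise of sd ``noise_sd`` cycles is added to every Ct measurement.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(rng_seed, "ct")
    rows = []
    for group, shift in ((reference_group, 0.0), (case_group, group_log2_fold)):
        for i in range(1, n_per_group + 1):
            rows.append(
                {
                    "sample_id": f"{group}-{i:03d}",
                    "group": group,
                    target: base_target_ct - shift + rng.normal(0.0, noise_sd),
                    normalizer: base_normalizer_ct + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


def gen_null_binder_sets(
    n_genes: int,
    binder_size: int,
    universe: Sequence[str],
    rng_seed: int = 0,
) -> dict[str, set[str]]:
    """Fully null binder sets: each gene binds ``binder_size`` miRNAs drawn
    uniformly without replacement — exactly the drawing-lots null."""
    rng = _rng(rng_seed, "misc")
    universe = sorted(universe)
    width = len(str(n_genes))
    return {
        f"NULLGENE{i:0{width}d}": set(rng.choice(universe, size=binder_size, replace=False))
        for i in range(1, n_genes + 1)
    }


def default_demo_config(seed: int = 0, n_gene: int = 4000) -> SynthConfig:
    """Study-shaped demo: 2555 miRNAs with 25+25 planted tail hits, 180
    planted convergent genes among 832 siRNA hits, 41 active candidates.

    Binder counts are drawn once from 30..120 with small candidate
    overlaps (k = 1 + Binomial(3, 0.3)); the first planted gene is a
    strongly convergent "star" (b=12, k=4), emulating a gene bound by 4
    of the 41 candidate miRNAs.
    """
    rng = np.random.default_rng([int(seed), 99])
    width = len(str(n_gene))
    gene_ids = [f"GENE{i:0{width}d}" for i in range(1, n_gene + 1)]
    planted = [PlantedGene(gene_ids[0], binder_count=12, candidate_overlap=4)]
    for i in range(1, 180):
        b = int(rng.integers(30, 121))
        k = 1 + int(rng.binomial(3, 0.3))
        planted.append(PlantedGene(gene_ids[i], binder_count=b, candidate_overlap=min(k, b)))
    return SynthConfig(
        n_mirna=2555,
        n_gene=n_gene,
        n_algorithms=6,
        base_call_prob=0.01,
        agreement=0.75,
        consensus_min=4,
        n_sirna_hits=832,
        planted_genes=tuple(planted),
        n_planted_top=25,
        n_planted_bottom=25,
        planted_shift=10.0,
        rng_seed=int(seed),
    )


def write_dataset(
    config: SynthConfig,
    outdir: str | Path,
    n_active_candidates: int = 41,
    utr_mirna_seq: str | None = None,
) -> dict:
    """Write every pipeline input plus a ground-truth JSON sidecar.

    The candidate miRNAs passed to the call generator are the first
    ``n_active_candidates`` planted tail miRNAs, so the convergence stage
    recovers exactly that many active candidates.  Returns the ground
    truth dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    screen = gen_screen_scores(config)
    screen.to_csv(outdir / "screen_scores.tsv", sep="\t", index=False)

    planted_tail = config.planted_top_ids() + config.planted_bottom_ids()
    active = planted_tail[:n_active_candidates]
    inactive_tail = planted_tail[n_active_candidates:]
    calls = gen_prediction_calls(
        config, candidates=active, noncandidate_exclude=inactive_tail
    )
    calls.calls.to_csv(outdir / "prediction_calls.tsv", sep="\t", index=False)

    hits = gen_sirna_hits(config)
    (outdir / "sirna_hits.txt").write_text("\n".join(hits) + "\n")

    rng = _rng(config.rng_seed, "misc")
    mirna_seq = utr_mirna_seq or "".join(rng.choice(list("ACGU"), size=22))
    mirna = MiRNASeq(id="miR-4504-like", sequence=mirna_seq)
    hap = gen_variant_utr(
        length=2000, variant_pos=1000, mirna=mirna,
        planted_allele="alt", rng_seed=config.rng_seed, gene_id="FERMT2-like",
    )
    _write_fasta(outdir / "mirna.fasta", {mirna.id: mirna.sequence})
    _write_fasta(
        outdir / "utr_alleles.fasta",
        {f"{hap.gene_id}|ref": hap.ref_seq, f"{hap.gene_id}|alt": hap.alt_seq},
    )
    pd.DataFrame(
        [{"gene_id": hap.gene_id, "variant_pos": hap.variant_pos,
          "ref_allele": hap.ref_allele, "alt_allele": hap.alt_allele}]
    ).to_csv(outdir / "variant.tsv", sep="\t", index=False)

    pre, post = gen_puncta_pair(
        n_pre=500, connected_fraction=0.6, jitter_sd=0.1,
        n_distractor_post=50, rng_seed=config.rng_seed,
    )
    pre.to_frame().to_csv(outdir / "puncta_pre.tsv", sep="\t", index=False)
    post.to_frame().to_csv(outdir / "puncta_post.tsv", sep="\t", index=False)

    ct = gen_ct_table(rng_seed=config.rng_seed)
    ct.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)

    truth = {
        "rng_seed": config.rng_seed,
        "planted_top_mirnas": config.planted_top_ids(),
        "planted_bottom_mirnas": config.planted_bottom_ids(),
        "active_candidates": active,
        "planted_genes": [asdict(pg) for pg in config.planted_genes],
        "planted_binders": {
            g: [str(m) for m in ms]
            for g, ms in _planted_binders(config, active, inactive_tail).items()
        },
        "sirna_hits_contain_planted": True,
        "utr": {
            "gene_id": hap.gene_id, "variant_pos": hap.variant_pos,
            "planted_allele": "alt", "mirna_id": mirna.id,
        },
        "puncta": {"n_pre": 500, "connected_fraction": 0.6,
                   "jitter_sd": 0.1, "n_distractor_post": 50},
        "ct": {"group_log2_fold": 1.0, "noise_sd": 0.2},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth


def _write_fasta(path: Path, records: Mapping[str, str]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    seqio_write(recs, str(path), "fasta")
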