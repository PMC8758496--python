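"""End-to-end convergence analysis with a reproducible run manifest.

Stages: rank the miRNA screen and take the extreme tails -> consensus
target prediction (>=4 algorithms) -> intersect candidate-miRNA targets
with the siRNA hit list -> drawing-lots permutation enrichment with
Bonferroni correction.  Every run writes per-stage TSVs, a JSON manifest
(seed, parameters, input checksums, funnel counts) and a human-readable
summary of the Bonferroni-significant genes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .consensus import consensus_targets, converge_with_sirna
from .enrichment import bonferroni_adjust, permutation_enrichment_test, records_to_frame
from .io import read_id_list, read_prediction_calls, read_screen_table
from .screen import select_extremes

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters and input paths for a full convergence run.

    ``binder_mode`` selects whether per-gene binder sets for the
    enrichment stage come from the consensus (>= min_algorithms) or the
    union (>= 1 algorithm) of predictions.
    """

    screen_path: str
    calls_path: str
    sirna_hits_path: str
    outdir: str
    tail_fraction: float = 0.01
    min_algorithms: int = 4
    binder_mode: str = "consensus"
    n_draws: int = 1_000_000
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.binder_mode not in ("consensus", "union"):
            raise ValueError("binder_mode must be 'consensus' or 'union'")
        if not 0 <= self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in [0, 0.5)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full convergence analysis; returns the run directory.

    On a stage failure the exception names the stage; outputs written so
    far remain on disk next to an ``INCOMPLETE`` flag file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flag = outdir / "INCOMPLETE"
    flag.write_text("run in progress\n")

    manifest: dict = {
        "tool": "mirconverge",
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("screen", config.screen_path),
                ("calls", config.calls_path),
                ("sirna_hits", config.sirna_hits_path),
            )
        },
        "funnel": {},
    }

    stage = "select"
    try:
        screen = read_screen_table(config.screen_path)
        selected = select_extremes(screen, config.tail_fraction)
        selected.to_frame().to_csv(outdir / "selected.tsv", sep="\t", index=False)
        manifest["funnel"]["n_screened"] = len(screen)
        manifest["funnel"]["n_selected"] = selected.n_selected

        stage = "consensus"
        calls = read_prediction_calls(config.calls_path)
        min_alg = config.min_algorithms if config.binder_mode == "consensus" else 1
        cmap = consensus_targets(calls, min_algorithms=min_alg)
        cmap.pairs.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
        candidate_targets = cmap.genes_targeted_by(selected.candidate_ids)
        manifest["funnel"]["n_consensus_pairs"] = len(cmap.pairs)
        manifest["funnel"]["n_candidate_target_genes"] = len(candidate_targets)

        stage = "converge"
        sirna_hits = read_id_list(config.sirna_hits_path)
        conv = converge_with_sirna(cmap, selected.candidate_ids, sirna_hits)
        conv.to_frame().to_csv(outdir / "convergence.tsv", sep="\t", index=False)
        manifest["funnel"]["n_convergent_genes"] = len(conv.genes)
        manifest["funnel"]["n_active_candidates"] = len(conv.active_candidates)

        stage = "enrich"
        universe = screen["entity_id"].tolist()
        records = []
        if conv.genes:
            binder_sets = cmap.binder_sets(universe=universe)
            records = permutation_enrichment_test(
                {g: binder_sets.get(g, set()) for g in conv.genes},
                universe=universe,
                candidates=conv.active_candidates,
                n_draws=config.n_draws,
                rng_seed=config.rng_seed,
                alpha=config.alpha,
            )
        df = records_to_frame(records)
        df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    threshold = config.alpha / len(records) if records else float("nan")
    significant = [r for r in records if r.p_emp < threshold] if records else []
    manifest["funnel"]["n_significant_genes"] = len(significant)
    manifest["enrichment"] = {
        "n_draws": config.n_draws,
        "rng_seed": config.rng_seed,
        "bonferroni_threshold": threshold,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    lines = [
        "mirconverge convergence analysis",
        f"screened entities:           {manifest['funnel']['n_screened']}",
        f"tail-selected candidates:    {manifest['funnel']['n_selected']}",
        f"candidate-target genes:      {manifest['funnel']['n_candidate_target_genes']}",
        f"convergent genes:            {manifest['funnel']['n_convergent_genes']}",
        f"active candidate miRNAs:     {manifest['funnel']['n_active_candidates']}",
        "",
    ]
    if records:
        lines.append(
            f"Bonferroni threshold (alpha={config.alpha}, G={len(records)}): "
            f"{threshold:.3e}"
        )
        if significant:
            lines.append("genes below the Bonferroni threshold:")
            lines += [
                f"  {r.gene_id}  k_obs={r.k_obs} b={r.b} p_emp={r.p_emp:.3e} "
                f"p_exact={r.p_exact:.3e}"
                for r in significant
            ]
        else:
            lines.append("no gene passes the Bonferroni threshold")
    else:
        lines.append("no convergent genes; enrichment stage skipped")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")

    flag.unlink()
    return outdir
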