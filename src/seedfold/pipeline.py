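"""End-to-end orchestration of the discovery and cooperation analyses.

``run_discovery`` chains seed-site prediction -> window extraction ->
overlap thinning -> accessibility scoring and ranking -> binding-site
masking -> k-mer motif discovery -> motif clustering, writing TSV reports
and a machine-readable run manifest.  ``run_cooperation`` consumes an
accessibility ranking plus expression matrices and runs the kd-tree sample
ordering, best-configuration search, single-regulator comparisons, and the
random-subset empirical null.  Both are plain library functions driven by a
:class:`PipelineConfig` (loadable from YAML); reports go to files, logging
to the standard logging machinery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .accessibility import rank_windows
from .expression import (
    choose_best_configuration, order_samples, random_subset_null, sample_points,
)
from .io import (
    read_expression_tsv, read_seed_table, read_site_table, read_utr_fasta,
)
from .motif_clustering import cluster_motifs, cluster_report
from .motif_discovery import (
    discover_motifs, mask_for_search, motif_report, occurrence_matrix,
)
from .sequence_sites import (
    extract_window, find_seed_sites, maximal_independent_set,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the published pipeline's stated values."""

    utr_fasta: str = ""
    seeds_tsv: str = ""
    sites_tsv: str | None = None
    mrna_tsv: str = ""
    mirna_tsv: str = ""
    mirna_id: str = ""
    rbp_id: str = ""
    out_dir: str = "seedfold_out"
    flank: int = 70
    mask_width: int = 25
    k: int = 9
    score_threshold: float = 1e-4
    min_support: int = 5
    min_start_distance: int = 100
    phi_fraction: float = 0.2
    n_draws: int = 1000
    diameter: float = 3.0
    backend: str = "internal"
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_manifest(config: PipelineConfig, out: Path, stage: str) -> None:
    manifest = {
        "stage": stage,
        "seedfold_version": __version__,
        "parameters": asdict(config),
    }
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def run_discovery(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Sites -> windows -> MIS -> scores -> rank -> mask -> discover -> cluster.

    Reports are returned keyed by name and written as TSV under
    ``config.out_dir`` together with a run manifest.  Any stage failure
    raises with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    utrs = read_utr_fasta(config.utr_fasta)
    families = read_seed_table(config.seeds_tsv)

    reports: dict[str, pd.DataFrame] = {}
    for family in families:
        tag = family.family_name
        try:
            if config.sites_tsv:
                utr_by_id = {u.gene_id: u for u in utrs}
                sites = [
                    s for s in read_site_table(config.sites_tsv)
                    if s.gene_id in utr_by_id
                ]
            else:
                sites = [
                    s for u in utrs for s in find_seed_sites(u, family)
                ]
                utr_by_id = {u.gene_id: u for u in utrs}
            windows = [
                w
                for s in sites
                if (w := extract_window(utr_by_id[s.gene_id], s, config.flank))
                is not None
            ]
            windows = maximal_independent_set(windows, config.min_start_distance)
            if len(windows) < 2:
                raise ValueError(f"fewer than 2 usable windows for {tag}")
            ranked, folds = rank_windows(
                windows, backend=config.backend, mask_width=config.mask_width
            )
            masked = [
                mask_for_search(w, folds[w.window_id]) for w in ranked.windows
            ]
            hits = discover_motifs(
                masked,
                k=config.k,
                score_threshold=config.score_threshold,
                min_support=config.min_support,
            )
            clusters = cluster_motifs([h.motif for h in hits], config.diameter)
        except Exception as exc:
            raise RuntimeError(f"discovery failed for family {tag}: {exc}") from exc
        reports[f"{tag}_scores"] = ranked.to_frame()
        reports[f"{tag}_motifs"] = motif_report(hits, k=config.k)
        reports[f"{tag}_clusters"] = cluster_report(clusters, config.diameter)
        reports[f"{tag}_occurrences"] = occurrence_matrix(masked, hits)
    for name, df in reports.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=name.endswith("occurrences"))
    _write_manifest(config, out, "discovery")
    return reports


def run_cooperation(
    config: PipelineConfig, scores_tsv: str | Path | None = None
) -> pd.DataFrame:
    """Φ definition -> kd ordering -> best configuration -> controls -> null.

    ``scores_tsv`` is a ranked scores report from :func:`run_discovery`
    (defaults to the single ``*_scores.tsv`` in ``config.out_dir``).  The
    returned summary holds the joint-ordering enrichment p, both
    single-regulator p's, the chosen k, and the empirical null p.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scores_tsv is None:
        candidates = sorted(out.glob("*_scores.tsv"))
        if len(candidates) != 1:
            raise ValueError(
                "pass scores_tsv explicitly; found "
                f"{len(candidates)} ranked score reports in {out}"
            )
        scores_tsv = candidates[0]
    scores = pd.read_csv(scores_tsv, sep="\t").sort_values("rank")
    ranked_genes = list(scores.gene_id)
    mrna = read_expression_tsv(config.mrna_tsv)
    mirna = read_expression_tsv(config.mirna_tsv)
    targets = [g for g in ranked_genes if g in mrna.index]
    n_phi = int(config.phi_fraction * len(ranked_genes))
    phi = [g for g in ranked_genes[:n_phi] if g in mrna.index]
    points = sample_points(mirna, mrna, config.mirna_id, config.rbp_id)

    rows = []
    traces = {}
    for mode in ("joint", "mirna", "rbp"):
        ordered = order_samples(points, mode)
        cfg, res, trace = choose_best_configuration(mrna, targets, ordered, phi)
        traces[mode] = trace
        rows.append((mode, cfg.k, res.score, res.p_value))
    summary = pd.DataFrame(
        rows, columns=["ordering", "best_k", "mhg_score", "p_value"]
    )
    joint_p = float(summary.loc[summary.ordering == "joint", "p_value"].iloc[0])
    null_p = random_subset_null(
        mrna, targets, order_samples(points, "joint"), phi,
        n_draws=config.n_draws, seed=config.seed,
    )
    summary["empirical_null_p"] = [null_p, None, None]
    # resolution floor: an empirical p of 0 means "< 1/n_draws"
    summary.attrs["null_resolution"] = 1.0 / config.n_draws
    for mode, trace in traces.items():
        trace.to_csv(out / f"cooperation_trace_{mode}.tsv", sep="\t", index=False)
    summary.to_csv(out / "cooperation_summary.tsv", sep="\t", index=False)
    _write_manifest(config, out, "cooperation")
    logger.info("joint ordering p=%.3g, empirical null p=%.3g", joint_p, null_p)
    return summary
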