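"""End-to-end benchmark: simulate → score → evaluate → FPR → networks.

The benchmark emulates the fidelity study design: an ensemble of disjoint
1000-gene groups, each with a full-quality reference (338 samples by
default) and nested low-quality subsamples (10/20/50 samples).  Every
group × quality matrix is scored with a base correlation weight and with
the wTO of that weight; fidelity of each low-quality score vector to its
full-quality reference is measured by rank agreement and top-k Jaccard,
and per-group differences between wTO and base fidelity are tested with
the Wilcoxon signed-rank test.  Independent stages add the null-data
false-positive-rate experiment and hard-threshold network topology
summaries.

All stages are deterministic functions of the configuration, including its
seed; :func:`run_benchmark` writes tidy TSV tables plus a JSON manifest
recording configuration and library versions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coexpression import (
    WeightMatrix,
    bicor_matrix,
    soft_threshold,
    spearman_matrix,
)
from .expression import ExpressionMatrix, read_expression
from .fidelity import (
    jaccard_top_k,
    paired_difference_test,
    rank_agreement,
    score_vector,
)
from .fpr import REFERENCE_CUTOFFS, run_fpr_experiment
from .networks import build_top_fraction_network, hub_overlap, summarize_network
from .simulate import (
    EnsembleDesign,
    child_seed,
    generate_modular_expression,
    generate_random_expression,
    nested_subsample,
    partition_genes,
)
from .wto import wto_matrix

__all__ = [
    "BenchmarkConfig",
    "generate_groups",
    "score_weights",
    "evaluate_ensemble",
    "compare_methods",
    "network_stage",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

_METRICS = {"spearman": spearman_matrix, "bicor": bicor_matrix}


@dataclass(frozen=True)
class BenchmarkConfig:
    """Full configuration of one benchmark run.

    ``mode`` selects the data source: ``modular`` plants correlated gene
    blocks (latent-factor model), ``uniform`` draws truth-free i.i.d.
    data, ``file`` reads an expression TSV from ``input_path`` and
    partitions its genes into the ensemble groups.

    In modular mode each group carries ``n_blocks`` planted modules of
    ``block_size`` genes; the remaining genes are independent noise.  The
    default (20 modules of 20 genes in a 1000-gene group) leaves most
    genes outside any module, as in real tissue transcriptomes, where
    tightly co-expressed modules cover only a minority of genes.
    """

    mode: str = "modular"
    input_path: str | None = None
    n_groups: int = 20
    group_size: int = 1000
    n_samples: int = 338
    n_blocks: int = 20
    block_size: int = 20
    rho: float = 0.7
    qualities: tuple[int, ...] = (10, 20, 50)
    metric: str = "bicor"
    soft_power: float = 1.0
    top_k: int = 1000
    network_fraction: float = 0.002
    percentiles: tuple[int, ...] = (90, 95, 99)
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.mode not in ("modular", "uniform", "file"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.mode == "file" and not self.input_path:
            raise ValueError("mode 'file' requires input_path")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["qualities"] = list(self.qualities)
        d["percentiles"] = list(self.percentiles)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("qualities", "percentiles"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def generate_groups(config: BenchmarkConfig) -> list[ExpressionMatrix]:
    """Materialise the ensemble groups prescribed by the configuration.

    Generated modes draw each group from an independent child stream of the
    root seed, so the ensemble size never perturbs individual groups; file
    mode shuffles the input's genes once and cuts disjoint groups.
    """
    if config.mode == "file":
        matrix = read_expression(config.input_path)
        design = EnsembleDesign(
            n_groups=config.n_groups,
            group_size=config.group_size,
            seed=config.seed,
        )
        return partition_genes(matrix, design)
    groups = []
    for g in range(config.n_groups):
        seed_g = child_seed(config.seed, g, f"group-data-{config.mode}")
        if config.mode == "uniform":
            groups.append(
                generate_random_expression(
                    config.group_size, config.n_samples, seed=seed_g
                )
            )
        else:
            groups.append(
                generate_modular_expression(
                    config.group_size,
                    config.n_samples,
                    block_sizes=[config.block_size] * config.n_blocks,
                    within_block_correlation=config.rho,
                    seed=seed_g,
                )
            )
    return groups


def score_weights(
    X: ExpressionMatrix, metric: str = "bicor", soft_power: float = 1.0
) -> WeightMatrix:
    """Base-correlation weight matrix: |corr|^soft_power, zero diagonal."""
    return soft_threshold(_METRICS[metric](X), beta=soft_power)


def evaluate_ensemble(
    groups: list[ExpressionMatrix],
    qualities: tuple[int, ...] = (10, 20, 50),
    metric: str = "bicor",
    soft_power: float = 1.0,
    top_k: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fidelity of low-quality base and wTO scores to full-quality references.

    For every group, the full matrix provides the reference base-weight and
    reference wTO score vectors; each nested low-quality level is scored
    the same way and compared with its own reference (base vs base, wTO vs
    wTO).  Returns one tidy row per (group, quality, score type).
    """
    rows = []
    for g, full in enumerate(groups):
        nested = nested_subsample(
            full, sorted(qualities), seed=child_seed(seed, g, "subsample")
        )
        W_ref = score_weights(full, metric, soft_power)
        ref_base = score_vector(W_ref)
        ref_wto = score_vector(wto_matrix(W_ref))
        for quality, level in nested.levels.items():
            W_low = score_weights(level, metric, soft_power)
            for tag, low, ref in (
                (metric, score_vector(W_low), ref_base),
                (f"wto-{metric}", score_vector(wto_matrix(W_low)), ref_wto),
            ):
                rows.append(
                    {
                        "group": g,
                        "quality": quality,
                        "metric": tag,
                        "soft_power": soft_power,
                        "rank_agreement": rank_agreement(low, ref),
                        "jaccard_top_k": jaccard_top_k(low, ref, k=top_k),
                        "k": top_k,
                    }
                )
        logger.info("evaluated group %d/%d", g + 1, len(groups))
    return pd.DataFrame(rows)


def compare_methods(
    fidelity: pd.DataFrame,
    statistic: str = "rank_agreement",
    exact: bool = True,
) -> pd.DataFrame:
    """Paired wTO-minus-base comparison per quality (Wilcoxon signed-rank).

    ``fidelity`` is the tidy table from :func:`evaluate_ensemble`; for each
    quality the per-group differences in ``statistic`` between the wTO and
    base rows are tested two-sided.  Returns one row per quality with the
    number of groups where wTO is superior and the p-value.
    """
    base_tags = sorted(t for t in fidelity.metric.unique() if not t.startswith("wto-"))
    if len(base_tags) != 1:
        raise ValueError(f"expected one base metric, found {base_tags}")
    base_tag = base_tags[0]
    wto_tag = f"wto-{base_tag}"
    rows = []
    for quality, sub in fidelity.groupby("quality"):
        piv = sub.pivot(index="group", columns="metric", values=statistic)
        diffs = (piv[wto_tag] - piv[base_tag]).to_numpy()
        p_value, n_positive = paired_difference_test(diffs, exact=exact)
        rows.append(
            {
                "quality": int(quality),
                "statistic": statistic,
                "n_groups": diffs.size,
                "n_superior_wto": n_positive,
                "mean_difference": float(diffs.mean()),
                "p_value": p_value,
            }
        )
    return pd.DataFrame(rows)


def network_stage(
    groups: list[ExpressionMatrix],
    qualities: tuple[int, ...] = (10, 20, 50),
    metric: str = "spearman",
    soft_power: float = 1.0,
    fraction: float = 0.002,
    seed: int = 0,
) -> pd.DataFrame:
    """Hard-threshold network summaries per (group, quality ∪ full, score).

    Each network keeps the top ``fraction`` of pairs; hub overlap is always
    measured against the group's full-quality base-correlation network, the
    reference a practitioner would trust most.
    """
    rows = []
    for g, full in enumerate(groups):
        nested = nested_subsample(
            full, sorted(qualities), seed=child_seed(seed, g, "subsample")
        )
        levels = dict(nested.levels)
        levels[full.n_samples] = full
        ref_summary = None
        for quality in sorted(levels):
            level = levels[quality]
            W = score_weights(level, metric, soft_power)
            for tag, sv in (
                (metric, score_vector(W)),
                (f"wto-{metric}", score_vector(wto_matrix(W))),
            ):
                graph = build_top_fraction_network(sv, fraction)
                summary = summarize_network(
                    graph, seed=child_seed(seed, g, f"louvain-{quality}-{tag}")
                )
                if quality == full.n_samples and tag == metric:
                    ref_summary = summary
                rows.append(
                    {
                        "group": g,
                        "quality": quality,
                        "metric": tag,
                        "n_nodes": summary.n_nodes,
                        "n_edges": summary.n_edges,
                        "avg_degree": summary.avg_degree,
                        "avg_clustering": summary.avg_clustering,
                        "degree_assortativity": summary.degree_assortativity,
                        "n_communities": summary.n_communities,
                        "modularity": summary.modularity,
                        "_summary": summary,
                    }
                )
        # reference exists by construction: the full-quality base row above
        for row in rows:
            if row["group"] == g and "hub_overlap_vs_reference" not in row:
                row["hub_overlap_vs_reference"] = hub_overlap(
                    row.pop("_summary"), ref_summary
                )
    return pd.DataFrame(rows)


def run_benchmark(config: BenchmarkConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write tidy TSV tables plus a manifest.

    Outputs in ``config.out_dir``: ``fidelity.tsv`` (per group × quality ×
    score fidelity), ``comparison.tsv`` (per-quality Wilcoxon results),
    ``fpr.tsv`` (null-data false-positive rates at the reference cutoffs),
    ``networks.tsv`` (topology summaries) and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s finished in %.1fs", name, timings[name])
        return result

    groups = _stage("simulate", lambda: generate_groups(config))
    fidelity = _stage(
        "evaluate",
        lambda: evaluate_ensemble(
            groups,
            qualities=config.qualities,
            metric=config.metric,
            soft_power=config.soft_power,
            top_k=config.top_k,
            seed=config.seed,
        ),
    )
    comparison = _stage("compare", lambda: compare_methods(fidelity))
    fpr_result = _stage(
        "fpr",
        lambda: run_fpr_experiment(
            EnsembleDesign(
                n_groups=config.n_groups,
                group_size=config.group_size,
                seed=child_seed(config.seed, 0, "fpr-experiment"),
            ),
            qualities=tuple(config.qualities) + (config.n_samples,),
            percentiles=config.percentiles,
            cutoffs={
                p: REFERENCE_CUTOFFS[p]
                for p in config.percentiles
                if p in REFERENCE_CUTOFFS
            }
            or None,
        ),
    )
    networks = _stage(
        "network",
        lambda: network_stage(
            groups,
            qualities=config.qualities,
            metric=config.metric,
            soft_power=config.soft_power,
            fraction=config.network_fraction,
            seed=config.seed,
        ),
    )

    tables = {
        "fidelity": fidelity,
        "comparison": comparison,
        "fpr": fpr_result.table,
        "fpr_per_group": fpr_result.per_group,
        "networks": networks,
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "config": json.loads(json.dumps(asdict(config))),
        "stage_seconds": timings,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return tables


def _versions() -> dict[str, str]:
    import networkx
    import scipy

    from . import __version__

    return {
        "wtofid": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }
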