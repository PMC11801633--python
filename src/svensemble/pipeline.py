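"""End-to-end orchestration: simulate → refine → merge → benchmark → report.

This is the library core behind the ``run-all`` CLI command and is what the
reproduction script drives.  Given a seed it generates ``n_datasets``
synthetic datasets (truth plus five caller call sets written and re-read as
VCF, exercising the full dialect round trip), refines every call set,
builds the III/V panel combinations under the requested strategies, scores
every single caller and combination against the truth per SV type, and
writes per-dataset, combined, concordance, and neighbor-distance tables.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bench import (
    ConfusionCounts,
    combine_micro,
    evaluation_report,
    match_to_truth,
)
from .merge import (
    concordance_counts,
    group_distance_summary,
    group_neighbors,
    apply_strategy,
)
from .records import PANELS, RefineConfig, StrategyConfig, SVRecord
from .refine import refine_vcf
from .simulate import (
    CallerProfile,
    SimConfig,
    default_profiles,
    simulate_call_sets,
)
from .vcfio import write_vcf

__all__ = ["RunResult", "run_all", "DEFAULT_STRATEGIES"]

DEFAULT_STRATEGIES = ("multiple_agreement", "union")


@dataclass
class RunResult:
    """Everything a full synthetic run produced."""

    counts: list[ConfusionCounts] = field(default_factory=list)
    reports: dict[str, pd.DataFrame] = field(default_factory=dict)
    concordance: dict[tuple[str, str], dict] = field(default_factory=dict)
    distances: dict[tuple[str, str, str], Optional[dict]] = field(
        default_factory=dict
    )
    refined_sizes: dict[tuple[str, str], int] = field(default_factory=dict)

    def combined(self, callset: str, svtype: str):
        sub = [
            c for c in self.counts
            if c.callset == callset and c.svtype == svtype
        ]
        return combine_micro(sub)


def _dataset_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence([int(seed), int(index)]).generate_state(1)
    return int(state[0] % (2**31 - 1))


def _strategy_label(panel_name: str, strategy: str) -> str:
    suffix = {
        "multiple_agreement": "multiple agreement",
        "union": "union",
        "direct_merge": "direct merge",
    }[strategy]
    return f"{panel_name}-{suffix}"


def run_all(
    seed: int,
    out_dir: Optional[str] = None,
    n_truth: int = 500,
    n_datasets: int = 4,
    panels: Sequence[str] = ("III", "V"),
    strategies: Sequence[str] = DEFAULT_STRATEGIES,
    window: int = 500,
    min_size: int = 50,
    min_support: int = 2,
    profiles: Optional[Sequence[CallerProfile]] = None,
    svtypes: Sequence[str] = ("DEL", "INS"),
    contigs: Optional[Sequence[tuple[str, int]]] = None,
) -> RunResult:
    """Run the whole synthetic analysis; write reports when ``out_dir`` set."""
    if profiles is None:
        profiles = default_profiles()
    refine_cfg = RefineConfig(min_size=min_size)
    result = RunResult()
    scratch = out_dir

    for d in range(n_datasets):
        label = f"SIM{d + 1}"
        sim_kwargs = dict(n_truth=n_truth, seed=_dataset_seed(seed, d))
        if contigs is not None:
            sim_kwargs["contigs"] = tuple(contigs)
        sim_cfg = SimConfig(**sim_kwargs)
        truth, call_sets = simulate_call_sets(sim_cfg, profiles)

        if scratch is not None:
            ds_dir = os.path.join(scratch, label)
            os.makedirs(ds_dir, exist_ok=True)
            write_vcf(truth, os.path.join(ds_dir, "truth.vcf"),
                      contigs=sim_cfg.contigs)
        refined: dict[str, list[SVRecord]] = {}
        for profile in profiles:
            dialect = "paired" if profile.emits_paired_records else "plain"
            if scratch is not None:
                raw_path = os.path.join(scratch, label,
                                        f"{profile.name}.vcf")
            else:
                import tempfile

                raw_path = os.path.join(
                    tempfile.mkdtemp(prefix="svensemble_"),
                    f"{profile.name}.vcf",
                )
            write_vcf(call_sets[profile.name], raw_path,
                      contigs=sim_cfg.contigs, dialect=dialect)
            records, _stats = refine_vcf(raw_path, profile.name, refine_cfg)
            refined[profile.name] = records
            result.refined_sizes[(label, profile.name)] = len(records)

        test_sets: dict[str, list[SVRecord]] = dict(refined)
        for panel_name in panels:
            panel = PANELS[panel_name]
            pooled = [r for name in panel for r in refined[name]]
            group_cfg = StrategyConfig(
                panel=panel, strategy="union",
                window=window, min_support=min_support,
            )
            groups = group_neighbors(pooled, group_cfg)
            result.concordance[(label, panel_name)] = concordance_counts(
                groups, group_cfg
            )
            for strategy in strategies:
                cfg = StrategyConfig(
                    panel=panel, strategy=strategy,
                    window=window, min_support=min_support,
                )
                merged = apply_strategy(groups, cfg, pooled=pooled)
                test_sets[_strategy_label(panel_name, strategy)] = merged
                result.distances[(label, panel_name, strategy)] = (
                    group_distance_summary(
                        groups if strategy != "multiple_agreement" else [
                            g for g in groups
                            if len(g.supporting_callers) >= min_support
                        ]
                    )
                )

        for callset, records in test_sets.items():
            for svtype in svtypes:
                test = [r for r in records if r.svtype == svtype]
                truth_t = [t for t in truth if t.svtype == svtype]
                result.counts.append(match_to_truth(
                    test, truth_t, svtype=svtype, window=window,
                    dataset=label, callset=callset,
                ))

    result.reports = evaluation_report(result.counts)
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result: RunResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for name, frame in result.reports.items():
        frame.to_csv(
            os.path.join(out_dir, f"metrics_{name}.tsv"),
            sep="\t", index=False, float_format="%.6f",
        )
    conc_rows = []
    for (dataset, panel), table in sorted(result.concordance.items()):
        for subset, count in sorted(
            table.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        ):
            conc_rows.append({
                "dataset": dataset, "panel": panel,
                "subset": ",".join(sorted(subset)), "count": count,
            })
    pd.DataFrame(conc_rows).to_csv(
        os.path.join(out_dir, "concordance.tsv"), sep="\t", index=False
    )
    dist_rows = []
    for (dataset, panel, strategy), summary in sorted(result.distances.items()):
        row = {"dataset": dataset, "panel": panel, "strategy": strategy}
        row.update(summary or {})
        dist_rows.append(row)
    pd.DataFrame(dist_rows).to_csv(
        os.path.join(out_dir, "group_distances.tsv"), sep="\t", index=False
    )
    metrics = {}
    for c in result.counts:
        from .bench import compute_metrics

        m = compute_metrics(c)
        metrics.setdefault(c.dataset, {}).setdefault(c.callset, {})[
            c.svtype
        ] = {
            "total": c.test_total, "tp": c.tp, "fp": c.fp, "fn": c.fn,
            "precision": m.precision, "recall": m.recall, "f1": m.f1,
        }
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
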