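"""End-to-end rehearsal of the full analysis on synthetic data.

Mirrors the shape of the real study at desk scale: screen a cohort with
one planted telomere-associated candidate and rank it; simulate a
knockout-vs-wildtype qPCR experiment with a telomere-lengthening effect
and test it one-sided; simulate knockout-vs-wildtype foci with elevated
colocalization and compare TIF-style ratios. Emits a single JSON report;
the same seed reproduces it byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .cohort import aggregate_targets, rank_and_call, summarize_distribution
from .foci import group_ratio_summary, match_foci_table
from .qpcr import compare_length_distributions, compute_ts_table
from .screen import DESK_QC, MotifSpec, screen_cohort, write_results
from .simulate import (
    CohortSimConfig,
    FociSimConfig,
    _child_seed,
    generate_cohort,
    generate_ct_table,
    generate_foci,
)

#: study conditions for the demo cohort: 20 targets x 3 replicates at a
#: 0.2% background repeat-read ratio, one candidate planted at 2%
DEMO_COHORT = dict(
    n_targets=20,
    replicates_per_target=3,
    background_ratio=0.002,
    tap_targets={"TAP1": 0.02},
    reads_per_sample=10_000,
    read_length=50,
)

#: knockout lengthens telomeres by one PCR cycle (deltaCt offset -1,
#: i.e. true T/S doubles); 20 samples per arm, 0.1-cycle pipetting noise
DEMO_CT = dict(n_per_group=20, groups={"WT": 0.0, "KO": -1.0}, noise_sd=0.1)

#: 30 nuclei per arm, 10 foci per channel, colocalized fraction 0.2 (WT)
#: vs 0.4 (KO), 0.2-unit jitter in a 100-unit field
DEMO_FOCI = dict(
    n_nuclei=30,
    field_size=100.0,
    foci_per_channel={"DAMAGE": 10, "TEL": 10},
    jitter_sd=0.2,
)
DEMO_FOCI_FRACTIONS = {"WT": 0.2, "KO": 0.4}
DEMO_FOCI_THRESHOLD = 1.5


def run_demo(seed: int, output_dir: str | Path) -> dict:
    """Run the full synthetic pipeline; returns (and writes) the report."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- screen: cohort with one planted candidate -------------------------
    cohort_dir = out / "cohort"
    manifest = generate_cohort(
        CohortSimConfig(seed=_child_seed(seed, 1), **DEMO_COHORT), cohort_dir
    )
    results = screen_cohort(manifest, MotifSpec(), qc=DESK_QC, base_dir=cohort_dir)
    write_results(results, out / "screen_results.tsv", manifest)
    ranked = rank_and_call(aggregate_targets(results, manifest))
    summary = summarize_distribution([s.score for s in ranked])
    top = ranked[0]
    screen_report = {
        "n_samples": len(results),
        "n_targets": len(ranked),
        "distribution": summary.to_dict(),
        "top_candidate": {
            "target": top.target,
            "score": top.score,
            "rank": top.rank,
            "is_outlier": top.is_outlier,
        },
        "ranking": [
            {"target": s.target, "score": s.score, "rank": s.rank,
             "is_outlier": s.is_outlier}
            for s in ranked
        ],
    }

    # -- telomere length: KO vs WT qPCR ------------------------------------
    ct = generate_ct_table(seed=_child_seed(seed, 2), **DEMO_CT)
    ts = compute_ts_table(ct)
    ts.to_csv(out / "ts_table.tsv", sep="\t", index=False)
    ko = ts.loc[ts["group"] == "KO", "t_s"].tolist()
    wt = ts.loc[ts["group"] == "WT", "t_s"].tolist()
    wilcoxon = compare_length_distributions(ko, wt, alternative="a_greater")
    length_report = {
        "mean_ts": {"KO": sum(ko) / len(ko), "WT": sum(wt) / len(wt)},
        "ts_fold_change_ko_vs_wt": (sum(ko) / len(ko)) / (sum(wt) / len(wt)),
        "wilcoxon": wilcoxon,
    }

    # -- foci: KO vs WT TIF-style colocalization ---------------------------
    coloc_by_group = {}
    for i, (group, frac) in enumerate(DEMO_FOCI_FRACTIONS.items()):
        table, _ = generate_foci(
            FociSimConfig(
                colocalized_fraction=frac,
                seed=_child_seed(seed, 3 + i),
                **DEMO_FOCI,
            )
        )
        table.to_csv(out / f"foci_{group}.tsv", sep="\t", index=False)
        coloc_by_group[group] = match_foci_table(
            table, channels=("DAMAGE", "TEL"), threshold=DEMO_FOCI_THRESHOLD,
            reference="TEL",
        )
    foci_report = group_ratio_summary(coloc_by_group)

    report = {
        "provenance": {"package": "teloscreen", "version": __version__, "seed": seed},
        "screen": screen_report,
        "telomere_length": length_report,
        "foci": foci_report,
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
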