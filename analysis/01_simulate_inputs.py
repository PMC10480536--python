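"""Generate every synthetic input the downstream analyses consume.

Produces, under scratch/analysis/ (large, regenerable, not tracked):
  - a screen cohort of 20 protein targets x 3 replicate read sets
    (10,000 reads each, 0.2% background repeat-read ratio) with one
    candidate, TAP1, planted at a 2% ratio;
  - a qPCR Ct table for a knockout-vs-wildtype comparison where the
    knockout lengthens telomeres by one PCR cycle (true T/S doubles);
  - two-channel foci tables (damage marker + telomere) for the same two
    arms, with the knockout's colocalized fraction doubled.

Run:  python analysis/01_simulate_inputs.py [--seed 0]
"""

import argparse
from pathlib import Path

from teloscreen import CohortSimConfig, FociSimConfig, generate_cohort, generate_foci
from teloscreen.simulate import _child_seed, generate_ct_table

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    cohort_cfg = CohortSimConfig(
        n_targets=20, replicates_per_target=3, background_ratio=0.002,
        tap_targets={"TAP1": 0.02}, reads_per_sample=10_000, read_length=50,
        seed=_child_seed(args.seed, 1),
    )
    manifest = generate_cohort(cohort_cfg, DATA / "cohort")
    print(f"cohort: {len(manifest)} samples -> {DATA / 'cohort'}")
    print("  planted candidate TAP1 at ratio 0.02 vs background 0.002")

    ct = generate_ct_table(
        20, {"WT": 0.0, "KO": -1.0}, noise_sd=0.1, base_ct=20.0,
        seed=_child_seed(args.seed, 2),
    )
    ct.to_csv(DATA / "ct_table.tsv", sep="\t", index=False)
    print(f"qPCR: {len(ct)} samples -> {DATA / 'ct_table.tsv'}  (true KO/WT T/S fold = 2)")

    for i, (group, frac) in enumerate({"WT": 0.2, "KO": 0.4}.items()):
        table, truth = generate_foci(
            FociSimConfig(
                n_nuclei=30, field_size=100.0,
                foci_per_channel={"DAMAGE": 10, "TEL": 10},
                colocalized_fraction=frac, jitter_sd=0.2,
                seed=_child_seed(args.seed, 3 + i),
            )
        )
        table.to_csv(DATA / f"foci_{group}.tsv", sep="\t", index=False)
        truth.to_csv(DATA / f"foci_{group}.truth.tsv", sep="\t", index=False)
        print(f"foci {group}: 30 nuclei, colocalized fraction {frac} -> foci_{group}.tsv")


if __name__ == "__main__":
    main()
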