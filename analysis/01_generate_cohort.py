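"""Generate the synthetic study cohort all downstream analyses run on.

Emulates the deposited behavioral tables: 30 participants, n-back
hit/false-alarm counts, practice-phase outcomes, and 64 final-test trials
each, with final-test success probabilities drawn from the reported
three-way-interaction coefficients.  Writes trials/nback/practice CSVs
plus the generating truth under results/data/.
"""

import argparse
import json
from pathlib import Path

from sacmem.io import RunManifest, validate_table
from sacmem.synth import GeneratorSpec, gen_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=30)
    ap.add_argument("--outdir", type=Path,
                    default=Path(__file__).resolve().parents[1]
                    / "results" / "data")
    args = ap.parse_args()

    spec = GeneratorSpec(n_participants=args.n, seed=args.seed)
    trials, nback, practice, truth = gen_cohort(spec)
    for name, table in (("trials", trials), ("nback", nback),
                        ("practice", practice)):
        validate_table(table, name)

    args.outdir.mkdir(parents=True, exist_ok=True)
    trials.to_csv(args.outdir / "trials.csv", index=False)
    nback.to_csv(args.outdir / "nback.csv", index=False)
    practice.to_csv(args.outdir / "practice.csv", index=False)
    (args.outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    manifest = RunManifest.create(truth, args.seed, "generate")
    for f in ("trials.csv", "nback.csv", "practice.csv"):
        manifest.record_output(args.outdir / f)
    manifest.save(args.outdir / "manifest.json")

    wm = trials.groupby("participant").wm_capacity.first()
    print(f"cohort: {args.n} participants, {len(trials)} final-test trials")
    print(f"WM capacity (n-back d'): mean {wm.mean():.2f}, SD {wm.std():.2f}")
    cells = trials.groupby(["frequency", "condition"]).final_correct.mean()
    print("cell accuracies:")
    print(cells.round(3).to_string())


if __name__ == "__main__":
    main()
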