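"""Build and optimize the central and peripheral treatment plans.

500 cGy is prescribed to the 240-point surface grid of the 35 mm
multichannel cylinder; dwell times come from geometric optimization with
a single global normalization.  Writes the plans (JSON) and dwell-time
tables (CSV) under results/.
"""

from pathlib import Path

from mcvcdose import (ApplicatorModel, example_source_model, make_plan,
                      mean_prescription_dose)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    source = example_source_model()
    applicator = ApplicatorModel()

    for loading in ("central", "peripheral"):
        plan = make_plan(source, applicator, loading)
        plan.to_json(OUT / f"plan_{loading}.json")
        plan.dwell_table().to_csv(OUT / f"dwells_{loading}.csv", index=False)
        t = plan.dwell_times
        print(f"{loading}: {len(plan.dwells)} dwells, "
              f"total time {t.sum():.1f} s, "
              f"end/middle time ratio {t.max() / t.min():.3f}, "
              f"mean prescription dose "
              f"{mean_prescription_dose(plan, source):.2f} cGy")


if __name__ == "__main__":
    main()
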