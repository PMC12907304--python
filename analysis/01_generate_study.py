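"""Simulate the virtual clinical study.

Generates one 20-subject virtual study under the reference elderly
population model — protocol dosing (0.4 mg/kg over 1 min, 0.8 mg/kg/h from
5 min), the 19-sample arterial schedule with synchronized BIS — and writes
the event-format dataset, the generating truth, and the population config
under results/.
"""

import pathlib

from ciprofol_pkpd import population, synthetic_study

SEED = 20260919
OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    pop = population.reference_population()
    design = synthetic_study.StudyDesign()
    study = synthetic_study.generate_study(design, pop, seed=SEED)
    synthetic_study.write_dataset(study, OUT / "study.csv", truth_path=OUT / "study_truth.json")
    population.save_config(pop, OUT / "population.yaml")
    obs = study.observations("pk")
    print(f"wrote {OUT/'study.csv'}: {len(study.df)} rows, "
          f"{len(obs)} PK observations ({int(obs.BLQ.sum())} BLQ), "
          f"{len(study.observations('pd'))} BIS observations from {len(study.subject_ids)} subjects")


if __name__ == "__main__":
    main()
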