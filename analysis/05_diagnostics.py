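"""Model qualification of the fitted PK model.

Computes the residual table (PRED/IPRED/CWRES/TAD), runs a subject-resampling
bootstrap (scaled down to 20 replicates with capped optimizer iterations so
the script stays interactive; the reference analysis used 1,000) and a
prediction-corrected VPC, writing tables and plots under results/.
"""

import pathlib

from ciprofol_pkpd import diagnostics, estimation, synthetic_study

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 20260920
N_BOOT = 20


def main():
    study = synthetic_study.read_dataset(OUT / "study.csv")
    fit = estimation.load_fit(OUT / "pk_fit_final.json")
    subjects = estimation.subjects_from_dataset(study, "pk")

    table = diagnostics.residual_table(fit, subjects)
    table.to_csv(OUT / "pk_residuals.csv", index=False)
    diagnostics.plot_gof(table, OUT / "pk_gof.png")
    print(f"residual table: {len(table)} rows; CWRES mean {table.CWRES.mean():+.3f}, sd {table.CWRES.std():.3f}")

    boot = diagnostics.bootstrap(
        study, n_reps=N_BOOT, seed=SEED,
        settings=estimation.FitSettings(outer_maxiter=30, max_restarts=1),
    )
    boot.summary.to_csv(OUT / "pk_bootstrap.csv")
    print(f"bootstrap: {boot.n_requested - boot.n_failed}/{boot.n_requested} converged")
    print(boot.summary.round(4).to_string())

    vpc = diagnostics.pc_vpc(subjects, fit, n_sim=200, bins=8, seed=SEED)
    vpc.table.to_csv(OUT / "pk_vpc.csv", index=False)
    diagnostics.plot_vpc(vpc, OUT / "pk_vpc.png", logy=True)
    print(f"pc-VPC: {vpc.coverage_fraction:.0%} of bin-percentiles inside the simulated bands")


if __name__ == "__main__":
    main()
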