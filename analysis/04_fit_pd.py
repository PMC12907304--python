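"""Sequential PD fit: effect-site sigmoid-Emax BIS model.

Fixes each subject's PK at the empirical-Bayes estimates of the final PK
fit, recomputes effect-site concentrations, and estimates ke0, E0, Emax,
EC50 and gamma (with IIV on EC50/gamma and additive BIS error) by FOCE-I.
"""

import pathlib

from ciprofol_pkpd import estimation, synthetic_study, workflows

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    study = synthetic_study.read_dataset(OUT / "study.csv")
    pk_fit = estimation.load_fit(OUT / "pk_fit_final.json")
    fit = estimation.fit_pd_sequential(study, pk_fit, init=workflows.perturbed_init())
    estimation.save_fit(fit, OUT / "pd_fit.json")
    print(f"PD model OFV {fit.ofv:.2f}  converged={fit.converged}")
    for k, v in fit.theta.items():
        print(f"  {k:6s} {v:10.4g}")
    print(f"  sigma2_pd {fit.sigma2:8.4g}")
    print("  eta-shrinkage (%):", {k: round(v, 1) for k, v in fit.eta_shrinkage.items()})


if __name__ == "__main__":
    main()
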