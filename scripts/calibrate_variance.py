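"""Calibration of the rater-cohort variance components.

The rating generator has two free dispersion parameters: the SD of the
participant random intercept on the rating-difference scale (sigma_u) and
the trial-level rating noise SD (sigma_t).  Everything else (slopes,
targeted means) is fixed by the published estimates.  Because ratings are
discretized to the 1-5 scale and clipped, the post-discretization moments
cannot be written in closed form, so the two SDs are chosen by a small grid
search against three published statistics, all computed on simulated data
exactly as the analysis pipeline computes them:

  * switcher targeted mean ratings (1.45 / 4.43, tolerance 0.05)
  * between-participant SD of the switcher targeted means (0.29-0.33)
  * conditional R^2 of the random-intercept fit on 11 x 25 switcher
    difference tables (0.74)

Run:  python scripts/calibrate_variance.py
"""

import dataclasses

import numpy as np

from bimeter.analysis import fit_random_intercept, rating_differences, targeted_means
from bimeter.raters import CohortConfig, generate_cohort, simulate_experiment

N_LARGE = 200          # cohort size for the mean/SD targets
N_REPS = 30            # replicate 11x25 fits for the R^2 target


def evaluate(sd_u: float, sd_t: float, seed: int = 12345) -> dict:
    base = CohortConfig(sd_intercept=sd_u, sd_rating_noise=sd_t)

    # large mixed cohort, 11:5 switcher proportion
    big = dataclasses.replace(
        base, n_per_group=(100, 25, 75), n_switchers=round(11 / 16 * N_LARGE)
    )
    cohort = generate_cohort(big, seed=seed)
    trials = simulate_experiment(cohort, seed=seed)
    sw = [p.id for p in cohort.switchers]
    tm_sw = targeted_means(trials, sw)
    tm_all = targeted_means(trials)

    # replicate switcher-only fits at study scale
    small = dataclasses.replace(base, n_per_group=(0, 0, 11), n_switchers=11)
    r2c, beta_d = [], []
    for rep in range(N_REPS):
        c = generate_cohort(small, seed=seed + rep)
        t = simulate_experiment(c, seed=seed + rep)
        fit = fit_random_intercept(rating_differences(t))
        r2c.append(fit.r2_glmm()[1])
        beta_d.append(fit.params[2])
    return {
        "sw_triple": tm_sw["triple_targeted"]["mean"],
        "sw_quad": tm_sw["quadruple_targeted"]["mean"],
        "sw_sd_triple": tm_sw["triple_targeted"]["sd"],
        "sw_sd_quad": tm_sw["quadruple_targeted"]["sd"],
        "all_triple": tm_all["triple_targeted"]["mean"],
        "all_quad": tm_all["quadruple_targeted"]["mean"],
        "r2_cond": float(np.mean(r2c)),
        "beta_d": float(np.mean(beta_d)),
    }


def main() -> None:
    print(
        f"{'sd_u':>5} {'sd_t':>5} {'sw_tri':>7} {'sw_quad':>8} "
        f"{'sd_tri':>7} {'sd_quad':>8} {'all_quad':>9} {'R2c':>6} {'beta_d':>9}"
    )
    for sd_u in (0.4, 0.5, 0.6):
        for sd_t in (0.5, 0.6, 0.7, 0.8, 0.9):
            m = evaluate(sd_u, sd_t)
            print(
                f"{sd_u:>5.2f} {sd_t:>5.2f} {m['sw_triple']:>7.3f} {m['sw_quad']:>8.3f} "
                f"{m['sw_sd_triple']:>7.3f} {m['sw_sd_quad']:>8.3f} "
                f"{m['all_quad']:>9.3f} {m['r2_cond']:>6.3f} {m['beta_d']:>9.5f}"
            )


if __name__ == "__main__":
    main()
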