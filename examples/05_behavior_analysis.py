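"""Synthetic same-different behavior and its link to classification errors.

Simulates the 4-block same-different categorization experiment from
distances in Weibull space, then correlates the mean behavioral confusion
matrix with the classification-error matrices of each statistic space
(Mantel test, diagonal excluded).  Because behavior is generated from
Weibull distances, the Weibull error pattern should correlate best.
"""

import argparse

import numpy as np

from deadleaves import (
    calibration,
    contrast,
    moments,
    similarity,
    simulate,
    spectra,
    stimuli,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    images = stimuli.generate_stimulus_set(master_seed=args.seed)
    labels = np.array([im.category_id for im in images])
    thr_b = calibration.default_thresholds(contrast.BETA_BANK)
    thr_g = calibration.default_thresholds(contrast.GAMMA_BANK)
    tables = {
        "weibull": contrast.weibull_stats_table(images, thr_b, thr_g)[["beta", "gamma"]],
        "fourier": spectra.fourier_stats_table(images)[["intercept", "slope"]],
        "moments": moments.moment_stats_table(images)[["skewness", "kurtosis"]],
    }

    z_weibull = similarity.normalize_params(tables["weibull"])
    dist = similarity.param_distance_matrix(z_weibull)
    behavior = simulate.generate_behavior(dist, labels, seed=args.seed)
    acc = behavior.subject_accuracy()
    print(
        f"simulated behavioral accuracy: mean {behavior.mean_accuracy:.2f}, "
        f"range {acc.min():.2f}-{acc.max():.2f} over {len(acc)} subjects"
    )

    print("\nMantel correlation of behavioral errors with classification errors:")
    for name, table in tables.items():
        res = similarity.loo_classify(similarity.normalize_params(table), labels)
        m = similarity.mantel_test(
            behavior.error_matrix,
            res.error_rate_matrix,
            n_permutations=2000,
            seed=args.seed,
        )
        print(f"  {name:8s} r_m = {m.r_m:+.2f} (p = {m.p_value:.4f})")


if __name__ == "__main__":
    main()
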