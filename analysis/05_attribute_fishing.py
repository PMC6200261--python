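#!/usr/bin/env python
"""Attribute prediction errors to fishing pressure; decompose skill by
time scale.

The lead-7 model deliberately carries no fishing information, so the
planted negative harvest effect (lag 2) must surface in the prediction
error: periods of low harvest rate let the stock outgrow the
hydrography-based prediction.  Also contrasts unfiltered skill with
high-pass (5-year cut-off) skill to show where the skill lives.
"""

from pathlib import Path

import numpy as np

from codcast.lags import peak_lag
from codcast.pipeline import (
    RunConfig,
    error_attribution,
    load_dataset,
    run_highpass_skill,
    run_prediction,
)
from codcast.series import to_anomalies

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = RunConfig(cv_n_iter=500, n_surrogates=500)
    dataset = load_dataset(config, seed=SEED)
    retro, _, _, _ = run_prediction(config, dataset, seed=SEED)
    observed_years = dataset["TSB"].years[dataset["TSB"].mask]
    observed = to_anomalies(dataset["TSB"], int(observed_years[0]),
                            int(observed_years[-1]))

    profile = error_attribution(retro, observed, dataset["HR"],
                                lag_range=config.attribution_lag_range,
                                n_surrogates=config.n_surrogates,
                                alpha=config.alpha, seed=SEED)
    OUT.mkdir(exist_ok=True)
    profile.to_frame().to_csv(OUT / "attribution.csv", index=False,
                              float_format="%.4g")
    lag, r = peak_lag(profile)
    flagged = profile.lags[profile.significant]
    print(f"harvest-rate vs prediction-error profile "
          f"(planted effect: lag 2, negative):")
    print(profile.to_frame().to_string(index=False))
    print(f"peak: r = {r:+.3f} at lag {lag}; "
          f"significant lags (family-wise): {list(flagged)}")

    r_full, r_high = run_highpass_skill(retro, observed,
                                        config.highpass_cutoff)
    print(f"skill decomposition: unfiltered r = {r_full:.3f}, "
          f"high-pass ({config.highpass_cutoff}-year cut-off) "
          f"r = {r_high:.3f}")


if __name__ == "__main__":
    main()
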