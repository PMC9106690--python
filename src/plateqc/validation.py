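"""Monte-Carlo validation of the pipeline against planted ground truth.

These helpers measure, under the generator's noise model, how well the
pipeline's estimators and filters recover what was planted: the sampling
behaviour of the n-replicate RSD, and the sensitivity / false-flag rate of
the MAD-based whole-sample outlier rule.  They are used by the test suite
and the acceptance script; problem sizes are arguments so callers choose
their own precision/runtime trade-off.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .panel import make_panel
from .qc import detect_sample_outliers, normalize_to_istd
from .simulate import ScenarioConfig, _lognormal, simulate_plate


def rsd_recovery(cv: float, n_replicates: int = 5, n_conditions: int = 2000,
                 seed: int | None = 0) -> float:
    """Median estimated percent RSD over many simulated conditions.

    Each condition draws ``n_replicates`` values from the generator's
    log-normal noise model with arithmetic CV ``cv`` and computes
    ``100 * sd / mean`` (sample sd, n-1 denominator); the median of those
    estimates is returned.  Note the small-sample estimator is biased low
    (E[s] < sigma), so the median sits below ``100 * cv`` at small n.
    """
    rng = np.random.default_rng(seed)
    draws = _lognormal(rng, 1.0, cv, size=(n_conditions, n_replicates))
    rsd = 100.0 * draws.std(axis=1, ddof=1) / draws.mean(axis=1)
    return float(np.median(rsd))


def outlier_detection_rates(n_seeds: int = 500, seed: int = 0,
                            outlier_scale: float = 10.0,
                            n_lc: int = 10, n_fia: int = 10,
                            replicates: int = 5,
                            config: RunConfig | None = None
                            ) -> tuple[float, float]:
    """Sensitivity and clean-replicate false-flag rate of outlier removal.

    Each seed simulates a two-condition plate (one condition with a planted
    whole-sample outlier at ``outlier_scale``, one clean), normalizes it and
    runs the MAD outlier rule.  Returns ``(sensitivity, false_flag_rate)``:
    the fraction of planted outliers removed, and the fraction of
    clean-condition replicates erroneously removed.
    """
    config = config or RunConfig()
    panel = make_panel({"amino acids": n_lc, "phosphatidylcholines": n_fia})
    hits = 0
    false_flags = 0
    clean_replicates = 0
    for i in range(n_seeds):
        scenario = ScenarioConfig(
            panel=panel, conditions=["planted", "clean"],
            replicates_per_condition=replicates,
            outlier_samples={("planted", 1): outlier_scale},
            seed=seed + i)
        dataset, truth = simulate_plate(scenario)
        meta = dataset.sample_meta()
        normalized = normalize_to_istd(dataset.sample_values(),
                                       dataset.istd.loc[meta.index],
                                       panel, audit=[])
        records = detect_sample_outliers(normalized, meta, panel, config)
        removed = {(r["condition"], r["replicate"], r["block"])
                   for r in records if r["removed"]}
        if any(c == "planted" and rep == 1 for c, rep, _ in removed):
            hits += 1
        # a clean datum is one (replicate, block) acquisition
        clean_replicates += 2 * replicates
        false_flags += sum(1 for (c, _, _) in removed if c == "clean")
    return hits / n_seeds, false_flags / clean_replicates
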