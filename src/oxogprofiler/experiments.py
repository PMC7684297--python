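"""Count-level Monte-Carlo experiments: null calibration and power checks.

These helpers run the whole analysis (simulate counts → normalize → sparse-bin
discard → per-chromosome totals → replicate means → paired signed-rank test)
on the fast count-level path of the simulator, so that hundreds or thousands
of replicate pipelines finish in seconds.  They are what the calibration
tests and the reproduction script drive.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .genome import GenomeModel
from .profiling import (
    ChromTotals,
    ConditionSummary,
    chrom_totals,
    condition_mean,
    normalize_and_filter,
)
from .simulate import IntensityMap, SimulationConfig, build_intensity_map, simulate_counts
from .stats import ComparisonReport, compare_conditions

__all__ = ["simulated_comparison", "rejection_rate"]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    states = [ss.generate_state(1)[0] % (2**31) for ss in np.random.SeedSequence(seed).spawn(n)]
    return [int(s) for s in states]


def simulated_comparison(
    genome: GenomeModel,
    config: SimulationConfig,
    condition_a: str = "wt",
    condition_b: str = "mut",
    n_replicates: int = 2,
    seed: int = 0,
    *,
    null: bool = False,
    bin_size: int = 10_000,
    min_hits: int = 10,
    scale: float = 1e6,
    alpha: float = 0.05,
    method: str = "auto",
    sidedness: str = "two-sided",
) -> ComparisonReport:
    """One full count-level pipeline run ending in a :class:`ComparisonReport`.

    Both conditions use intensity maps built from the *same* layout seed, so
    hotspot bins are shared; ``null=True`` additionally draws both conditions
    from condition_a's map (same expected signal, so any detected difference
    is a false positive).
    """
    map_a = build_intensity_map(genome, config, condition_a, seed=config.seed,
                                bin_size=bin_size)
    map_b = map_a if null else build_intensity_map(
        genome, config, condition_b, seed=config.seed, bin_size=bin_size
    )
    draw_seeds = _spawn_seeds(seed, 2 * n_replicates)
    summaries: list[ConditionSummary] = []
    for label, imap, seeds in (
        (condition_a, map_a, draw_seeds[:n_replicates]),
        (condition_b, map_b, draw_seeds[n_replicates:]),
    ):
        reps: list[ChromTotals] = []
        for r, s in enumerate(seeds, start=1):
            counts = simulate_counts(imap, config.n_reads_per_sample, seed=s)
            profile = normalize_and_filter(
                counts, scale=scale, min_hits=min_hits, sample=f"{label}_rep{r}"
            )
            reps.append(chrom_totals(profile))
        summaries.append(condition_mean(reps, condition=label))
    return compare_conditions(summaries[0], summaries[1], alpha=alpha,
                              method=method, sidedness=sidedness)


def rejection_rate(
    genome: GenomeModel,
    config: SimulationConfig,
    n_runs: int,
    seed: int,
    *,
    null: bool = True,
    alpha: float = 0.05,
    **kwargs,
) -> tuple[float, list[ComparisonReport]]:
    """Fraction of ``n_runs`` independent pipeline runs rejecting at ``alpha``."""
    run_seeds = _spawn_seeds(seed, n_runs)
    reports = [
        simulated_comparison(genome, config, seed=s, null=null, alpha=alpha, **kwargs)
        for s in run_seeds
    ]
    rate = float(np.mean([r.significant for r in reports]))
    return rate, reports
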