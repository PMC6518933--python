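"""Does the number of habitats or their total area predict richness better?

For every accumulation run, an additive penalized-spline model of richness
on site count and cumulative area is compared against its two drop-one
submodels; the predictor whose removal costs more explained deviance wins
the run. The percentage of runs won by habitat number is reported for each
epoch.

Writes: results/predictor_contest.json
"""

from pathlib import Path

from pondscape import io, rarefaction, smooths
from pondscape.pipeline import stage_seed

SEED = 1
N_RUNS = 500  # each run refits three GCV-selected spline models
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ponds = io.read_pond_table(ROOT / "case_study" / "ponds.csv")
    seed = stage_seed(SEED, "smooths")
    out = {}
    for epoch, occ_file in (("1957", "occ_1957.csv"), ("2010", "occ_2010.csv")):
        occ = io.read_occurrence_matrix(ROOT / "case_study" / occ_file, epoch, ponds)
        areas = ponds.areas(epoch, occ.site_ids)
        runs = rarefaction.accumulation_runs(occ, areas, n_runs=N_RUNS, seed=seed)
        contest = smooths.proportion_sites_better(smooths.compare_runs(runs))
        out[epoch] = {
            "pct_sites_better": contest.pct_sites_better,
            "n_sites": contest.n_sites,
            "n_area": contest.n_area,
            "n_tie": contest.n_tie,
        }
        print(f"{epoch}: habitat number wins {contest.pct_sites_better:.1f}% "
              f"of {N_RUNS} runs ({contest.n_tie} ties excluded)")
    io.write_results(out, ROOT / "predictor_contest.json", seed=SEED)


if __name__ == "__main__":
    main()
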