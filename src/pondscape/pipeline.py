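"""Full-analysis orchestration over real or synthetic two-epoch data.

Stage order mirrors the analysis: I/O (or synthetic generation) ->
rarefaction on both axes with expected losses -> habitat-number vs
habitat-area contest -> network connectivity change -> alpha/beta effect
sizes -> trait and local-driver models. One master seed is split
deterministically into per-stage streams so any stage can be re-run alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import diversity, drivers, io, landscape, network, rarefaction, smooths

log = logging.getLogger(__name__)

STAGES = ("landscape", "rarefaction", "smooths", "network", "diversity", "drivers")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed split from one master seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(master_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Everything a full analysis run needs, defaults made explicit."""

    # input tables; leave None to run on a synthetic case study
    ponds_path: str | None = None
    occ_1957_path: str | None = None
    occ_2010_path: str | None = None
    body_sizes_path: str | None = None
    synthetic: bool = True
    n_runs: int = 2000
    n_comparison_runs: int = 500  # per-run GAM refits dominate cost
    n_perm: int = 200
    qr_df: int = 5
    spline_k: int = 10
    seed: int = 0
    area_transform: Literal["log", "identity"] = "log"
    r2_variant: Literal["deviance", "variance"] = "deviance"
    out_dir: str | None = None

    def echo(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def load_inputs(config: RunConfig):
    if config.synthetic:
        case = landscape.generate_case_study(seed=stage_seed(config.seed, "landscape"))
        return case.ponds, case.occ_1957, case.occ_2010, case.body_sizes
    ponds = io.read_pond_table(config.ponds_path)
    occ_1957 = io.read_occurrence_matrix(config.occ_1957_path, "1957", ponds)
    occ_2010 = io.read_occurrence_matrix(config.occ_2010_path, "2010", ponds)
    body_sizes = io.read_body_sizes(config.body_sizes_path)
    return ponds, occ_1957, occ_2010, body_sizes


def site_change_records(
    ponds: io.PondTable,
    occ_1957: io.OccurrenceMatrix,
    occ_2010: io.OccurrenceMatrix,
    area_transform: Literal["log", "identity"] = "log",
) -> pd.DataFrame:
    """Per-pond change table at the ponds sampled in both epochs.

    d_closeness comes from the full extant networks of each epoch (116 vs 30
    nodes in the study's dimensions), not just the sampled subset.
    """
    shared = [s for s in occ_1957.site_ids if s in set(occ_2010.site_ids)]
    if not shared:
        raise io.DataError("no ponds sampled in both epochs")
    a1 = pd.Series(occ_1957.alpha, index=occ_1957.site_ids).loc[shared]
    a2 = pd.Series(occ_2010.alpha, index=occ_2010.site_ids).loc[shared]
    dclose = network.delta_closeness(
        network.build_network(ponds, "1957"), network.build_network(ponds, "2010"), shared
    )
    area1 = ponds.areas("1957", shared)
    area2 = ponds.areas("2010", shared)
    if area_transform == "log":
        d_area = np.log(area2) - np.log(area1)
    else:
        d_area = area2 - area1
    cond1 = ponds.conductivities("1957", shared)
    cond2 = ponds.conductivities("2010", shared)
    out = pd.DataFrame(
        {
            "d_richness": (a2 - a1).astype(float),
            "d_closeness": dclose,
            "d_conductivity": (cond2 - cond1).astype(float),
            "d_log_area": d_area.astype(float),
        },
        index=pd.Index(shared, name="pond_id"),
    )
    if out.isna().any().any():
        raise io.DataError("missing area/conductivity for a shared pond")
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage; returns (and optionally writes) the report bundle."""
    t0 = time.time()
    ponds, occ_1957, occ_2010, body_sizes = load_inputs(config)
    results: dict = {}

    def tick(stage):
        log.info("stage %-12s done at %.1fs", stage, time.time() - t0)

    gamma_1957, gamma_2010 = occ_1957.gamma, occ_2010.gamma
    sp1, sp2 = occ_1957.species_present, occ_2010.species_present
    results["richness"] = {
        "gamma_1957": gamma_1957,
        "gamma_2010": gamma_2010,
        "species_lost": len(sp1 - sp2),
        "species_gained": len(sp2 - sp1),
        "net_regional_loss": gamma_1957 - gamma_2010,
    }
    tick("io")

    seed_r = stage_seed(config.seed, "rarefaction")
    m_target = occ_2010.n_sites
    areas_1957 = ponds.areas("1957", occ_1957.site_ids)
    a_target = float(ponds.areas("2010", occ_2010.site_ids).sum())
    loss_sites = rarefaction.expected_loss_sites(
        occ_1957, m_target, n_runs=config.n_runs, seed=seed_r
    )
    loss_area = rarefaction.expected_loss_area(
        occ_1957, areas_1957, a_target,
        n_runs=config.n_runs, qr_df=config.qr_df, seed=seed_r + 1,
    )
    results["rarefaction"] = {
        "m_target": m_target,
        "a_target_ha": a_target,
        "expected_loss_sites": loss_sites.expected,
        "expected_loss_sites_rounded": loss_sites.rounded,
        "expected_loss_sites_ci": list(loss_sites.ci),
        "expected_loss_sites_analytic": loss_sites.analytic,
        "expected_loss_area": loss_area.expected,
        "expected_loss_area_rounded": loss_area.rounded,
        "expected_loss_area_ci": list(loss_area.ci),
        "n_runs": config.n_runs,
    }
    tick("rarefaction")

    seed_s = stage_seed(config.seed, "smooths")
    contest = {}
    for label, occ, areas in (
        ("1957", occ_1957, areas_1957),
        ("2010", occ_2010, ponds.areas("2010", occ_2010.site_ids)),
    ):
        runs = rarefaction.accumulation_runs(
            occ, areas, n_runs=config.n_comparison_runs, seed=seed_s
        )
        comp = smooths.compare_runs(runs, k=config.spline_k)
        c = smooths.proportion_sites_better(comp)
        contest[label] = {
            "pct_sites_better": c.pct_sites_better,
            "n_sites": c.n_sites,
            "n_area": c.n_area,
            "n_tie": c.n_tie,
            "n_runs": config.n_comparison_runs,
        }
    results["predictor_contest"] = contest
    tick("smooths")

    net_1957 = network.build_network(ponds, "1957")
    net_2010 = network.build_network(ponds, "2010")
    dclose = network.delta_closeness(net_1957, net_2010)
    results["network"] = {
        "n_nodes_1957": net_1957.n,
        "n_nodes_2010": net_2010.n,
        "mean_closeness_1957_km": float(network.closeness_index(net_1957).mean()),
        "mean_closeness_2010_km": float(network.closeness_index(net_2010).mean()),
        "mean_delta_closeness_km": float(dclose.mean()),
    }
    tick("network")

    seed_d = stage_seed(config.seed, "diversity")
    es_alpha = diversity.effect_size_alpha(occ_1957, occ_2010, config.n_perm, seed_d)
    es_beta = diversity.effect_size_beta(occ_1957, occ_2010, config.n_perm, seed_d + 1)
    results["diversity_change"] = {
        "mean_alpha_1957": es_alpha.value_a,
        "mean_alpha_2010": es_alpha.value_b,
        "beta_1957": es_beta.value_a,
        "beta_2010": es_beta.value_b,
        "d_bar_alpha": es_alpha.d_bar,
        "p_alpha": es_alpha.p_value,
        "d_bar_beta": es_beta.d_bar,
        "p_beta": es_beta.p_value,
        "n_perm": config.n_perm,
    }
    tick("diversity")

    traits = io.derive_species_traits(occ_1957, ponds, body_sizes, sp2)
    ext_part = drivers.commonality_partition(
        traits["extinct_2010"].astype(float),
        pd.DataFrame(
            {
                "sqrt_occupancy": np.sqrt(traits["occupancy_1957"]),
                "log_body_size": np.log(traits["body_size"]),
                "preference": traits["preference"],
            }
        ),
        family="binomial",
        r2_variant=config.r2_variant,
    )
    ext_fit = drivers.extinction_model(traits)
    records = site_change_records(ponds, occ_1957, occ_2010, config.area_transform)
    local = drivers.local_drivers_analysis(records)
    results["drivers"] = {
        "extinction_glm": {
            "coef": ext_fit.params.to_dict(),
            "p": ext_fit.pvalues.to_dict(),
            "converged": ext_fit.converged,
        },
        "extinction_pure_r2": {
            "sqrt_occupancy": ext_part.pure("sqrt_occupancy"),
            "log_body_size": ext_part.pure("log_body_size"),
            "preference": ext_part.pure("preference"),
        },
        "local_pure_r2": {
            "d_closeness": local.partition.pure("d_closeness"),
            "d_conductivity": local.partition.pure("d_conductivity"),
            "d_log_area": local.partition.pure("d_log_area"),
        },
        "local_slopes": local.slopes.to_dict(),
        "local_p": local.pvalues.to_dict(),
        "n_shared_sites": len(records),
        "mean_d_conductivity": float(records["d_conductivity"].mean()),
    }
    tick("drivers")

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_results(results, out / "results.json", seed=config.seed,
                         config=config.echo())
        records.to_csv(out / "site_changes.csv")
        traits.reset_index().to_csv(out / "traits.csv", index=False)
        dclose.rename("d_closeness_km").reset_index().to_csv(
            out / "delta_closeness.csv", index=False
        )
    return results


def make_fixture(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a synthetic case study as the CSV interchange files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # same seed split as run_full_analysis: one master seed, one world
    case = landscape.generate_case_study(seed=stage_seed(seed, "landscape"))
    paths = {
        "ponds": out / "ponds.csv",
        "occ_1957": out / "occ_1957.csv",
        "occ_2010": out / "occ_2010.csv",
        "body_sizes": out / "body_sizes.csv",
    }
    io.write_pond_table(case.ponds, paths["ponds"])
    io.write_occurrence_matrix(case.occ_1957, paths["occ_1957"])
    io.write_occurrence_matrix(case.occ_2010, paths["occ_2010"])
    case.body_sizes.reset_index().to_csv(paths["body_sizes"], index=False)
    return paths
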