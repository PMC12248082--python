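"""End-to-end seeded cohort studies: simulate -> analyze -> stats -> report.

A cohort study generates ``n`` synthetic control and ``n`` conditional
knockout arbors from the genotype presets, computes per-cell morphometry
and normalized Sholl profiles, then runs the group statistics: Student's
t-tests on scalar metrics, a Sholl AUC t-test, and Fisher's exact test on
hypertrophic-dendrite counts.  One master seed governs the run; per-cell
seeds are derived from it with ``numpy.random.SeedSequence`` so any single
cell can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .errors import ParameterError
from .morphometry import morphometry
from .synth import GENOTYPE_PRESETS, ArborGenParams, gen_arbor

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    n_control: int = 12
    n_cko: int = 16
    control_preset: str = "control"
    cko_preset: str = "pten_cko"
    overrides: dict = field(default_factory=dict)  # per-preset param overrides
    # force exact hypertrophic-cell counts per arm (e.g. the printed 1/12 vs
    # 13/16) instead of drawing them from the preset probability
    forced_hypertrophic: dict | None = None
    sholl_step: float = 2.0
    z_tol: float = 0.5
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for preset in (self.control_preset, self.cko_preset):
            if preset not in GENOTYPE_PRESETS:
                raise ParameterError(f"unknown genotype preset {preset!r}")
        if self.n_control < 2 or self.n_cko < 2:
            raise ParameterError("each cohort needs >= 2 cells")


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a TOML file (top-level ``[run]`` table)."""
    import tomllib

    data = tomllib.loads(Path(path).read_text())
    run = data.get("run", data)
    return RunConfig(**run)


def _cell_seeds(master_seed: int, label: str, n: int) -> list[int]:
    # crc32, not hash(): process-stable so runs are reproducible
    ss = np.random.SeedSequence([master_seed, zlib.crc32(label.encode())])
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def _cohort_params(preset_name: str, overrides: dict, n: int, master_seed: int,
                   forced_hyper: int | None) -> list[ArborGenParams]:
    preset = dict(GENOTYPE_PRESETS[preset_name])
    preset.update(overrides.get(preset_name, {}))
    hyper_prob = preset.pop("hypertrophic_prob", 0.0)
    seeds = _cell_seeds(master_seed, preset_name, n)
    hyper_rng = np.random.default_rng(_cell_seeds(master_seed, preset_name + "/hyper", 1)[0])
    if forced_hyper is not None:
        if not 0 <= forced_hyper <= n:
            raise ParameterError("forced hypertrophic count outside cohort size")
        hyper_flags = [i < forced_hyper for i in range(n)]
    else:
        hyper_flags = [bool(hyper_rng.random() < hyper_prob) for _ in range(n)]
    return [
        ArborGenParams(seed=s, hypertrophic=h, **preset)
        for s, h in zip(seeds, hyper_flags)
    ]


def run_cohort_study(config: RunConfig) -> dict:
    """Generate both cohorts, measure every cell, and compare the groups.

    Returns the report dict; when ``config.out_dir`` is set, also writes
    ``metrics.csv``, ``sholl.csv``, ``stats_report.json`` and ``run.log``.
    """
    cfg = config
    forced = cfg.forced_hypertrophic or {}
    arms = {
        "control": _cohort_params(cfg.control_preset, cfg.overrides, cfg.n_control,
                                  cfg.seed, forced.get("control")),
        "cko": _cohort_params(cfg.cko_preset, cfg.overrides, cfg.n_cko,
                              cfg.seed, forced.get("cko")),
    }

    rows, sholl_rows = [], []
    sholl_bins: dict[str, list[np.ndarray]] = {"control": [], "cko": []}
    for arm, params_list in arms.items():
        for i, params in enumerate(params_list):
            cell_id = f"{arm}_{i:03d}"
            try:
                arbor = gen_arbor(params)
                result, sholl = morphometry(arbor, sholl_step=cfg.sholl_step,
                                            z_tol=cfg.z_tol)
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'morphometry' failed for cell {cell_id} "
                    f"(seed {params.seed})"
                ) from exc
            row = {"cell_id": cell_id, "arm": arm, "seed": params.seed}
            row.update(dataclasses.asdict(result))
            rows.append(row)
            sholl_bins[arm].append(sholl.normalized_bins)
            sholl_rows.append({"cell_id": cell_id, "arm": arm,
                               **{f"bin_{k + 1}": v
                                  for k, v in enumerate(sholl.normalized_bins)}})
            logger.info("cell %s: length=%.1f branches=%d hyper=%s",
                        cell_id, result.total_length, result.n_branch_points,
                        result.is_hypertrophic)

    metrics = pd.DataFrame(rows)
    by_arm = {arm: metrics[metrics.arm == arm] for arm in ("control", "cko")}

    comparisons = {
        metric: st.group_compare(
            {arm: df[metric].to_numpy() for arm, df in by_arm.items()},
            design="two_group",
        )
        for metric in ("total_length", "n_branch_points", "field_area")
    }
    auc = st.sholl_auc_compare(sholl_bins["control"], sholl_bins["cko"])

    hyper = {arm: int(df.is_hypertrophic.sum()) for arm, df in by_arm.items()}
    table = st.ContingencyTable2x2(
        a=hyper["cko"], b=cfg.n_cko - hyper["cko"],
        c=hyper["control"], d=cfg.n_control - hyper["control"],
    )
    fisher_p = st.fisher_exact_two_sided(table)

    report = {
        "config": {
            "seed": cfg.seed, "n_control": cfg.n_control, "n_cko": cfg.n_cko,
            "control_preset": cfg.control_preset, "cko_preset": cfg.cko_preset,
        },
        "comparisons": comparisons,
        "sholl_auc": {k: v for k, v in auc.items()
                      if k not in ("auc_a", "auc_b")},
        "hypertrophic": {
            "control": f"{hyper['control']}/{cfg.n_control}",
            "cko": f"{hyper['cko']}/{cfg.n_cko}",
            "control_pct": 100.0 * hyper["control"] / cfg.n_control,
            "cko_pct": 100.0 * hyper["cko"] / cfg.n_cko,
            "fisher_p": fisher_p,
        },
    }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        pd.DataFrame(sholl_rows).to_csv(out / "sholl.csv", index=False)
        (out / "stats_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        logger.info("report written to %s", out)
    return report
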