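"""End-to-end orchestration: simulate -> features -> assemble -> select ->
associate -> agree, with a reproducibility manifest.

Stages hand off through plain files (CSV + JSON) in the run directory;
the manifest records the config hash, seed, stage order, SHA-256 digests
of every written file and any stage warnings, so a rerun with the same
config and seed reproduces byte-identical tabular outputs (timestamps in
the manifest aside).
"""

from __future__ import annotations

import hashlib
import json
import warnings as warnmod
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import assemble as asm
from . import association as assoc
from . import features as feat
from . import io as aio
from . import selection as selm
from .config import SimulationConfig
from .selection import SelectionConfig
from .simulate import simulate_diary, simulate_epoch_cohort

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    digests: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    warnings: list = field(default_factory=list)
    failure: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    sim_cfg: SimulationConfig,
    out_dir: str | Path,
    sel_cfg: SelectionConfig | None = None,
) -> RunManifest:
    """Execute all stages on a freshly simulated cohort.

    Any stage failure aborts the run with the failure recorded in the
    manifest (written regardless).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(sim_cfg.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        seed=sim_cfg.seed,
        started=datetime.now(timezone.utc).isoformat(),
    )
    if sel_cfg is None:
        sel_cfg = SelectionConfig(
            alpha_grid=(0.0, 0.5, 1.0),
            n_iterations=3,
            n_folds=5,
            n_lambda=5,
            seed=sim_cfg.seed,
        )

    def record(stage: str, *paths: Path) -> None:
        manifest.stages.append(stage)
        for p in paths:
            manifest.digests[p.name] = _sha256(p)

    try:
        with warnmod.catch_warnings(record=True) as caught:
            warnmod.simplefilter("always")

            # simulate
            series, truth = simulate_epoch_cohort(sim_cfg)
            diary = simulate_diary(truth, sim_cfg) if sim_cfg.sleep_dur_mu > 0 else pd.DataFrame()
            p_epochs = aio.write_epoch_table(series, out / "epochs.csv")
            aio.write_ground_truth(truth, out)
            p_diary = out / "diary.csv"
            diary.to_csv(p_diary, index=False, date_format="%Y-%m-%dT%H:%M:%S")
            record("simulate", p_epochs, p_diary)

            # features (includes preprocessing/QC per participant)
            day_table, qc_table = feat.extract_cohort(series, meta=truth.participants)
            p_days = out / "day_traits.csv"
            p_qc = out / "qc.csv"
            day_table.to_csv(p_days, index=False, date_format="%Y-%m-%d")
            qc_table.to_csv(p_qc, index=False)
            record("features", p_days, p_qc)
            if day_table.empty:
                raise RuntimeError("no participants passed QC")

            # assemble odd/even z-scored tables (identical column sets)
            odd_tab, even_tab = asm.assemble_parity_tables(day_table)
            tables = {"odd": odd_tab, "even": even_tab}
            for parity in ("odd", "even"):
                p = out / f"features_{parity}.csv"
                tables[parity].to_csv(p)
                record(f"assemble_{parity}", p)

            # selection: tune on odd, validate on even
            groups = tables["odd"]["group"].astype(str)
            if groups.nunique() < 2:
                raise RuntimeError("selection requires both classes present")
            best_alpha, dist = selm.tune_alpha(tables["odd"], sel_cfg)
            report, model = selm.fit_select(
                tables["odd"], best_alpha, sel_cfg, alpha_aucs=dist
            )
            report.auc_test = selm.evaluate_auc(model, tables["even"], sel_cfg)
            p_sel = out / "selection.json"
            p_sel.write_text(
                json.dumps(
                    {
                        "variant": report.variant,
                        "best_alpha": report.best_alpha,
                        "alpha_aucs": report.alpha_aucs,
                        "selected": report.selected,
                        "coefficients": report.coefficients.to_dict(),
                        "auc_train_odd": report.auc_train,
                        "auc_test_even": report.auc_test,
                    },
                    indent=2,
                )
            )
            record("select", p_sel)

            # association: day-level mixed model on derived traits
            assoc_df = day_table.dropna(subset=["total_sleep_time", "time_sedentary"]).copy()
            assoc_df["total_sleep_min"] = assoc_df["total_sleep_time"] * 60.0
            assoc_df = assoc_df.rename(columns={"time_sedentary": "sedentary_hours"})
            res = assoc.fit_day_level_model(
                assoc_df, outcome="total_sleep_min", exposure="sedentary_hours", do_lrt=False
            )
            p_assoc = out / "association.json"
            p_assoc.write_text(
                json.dumps(
                    {
                        "outcome": res.outcome,
                        "exposure": res.exposure,
                        "slope_case": res.slope_case,
                        "slope_control": res.slope_control,
                        "interaction": res.interaction,
                        "method": res.method,
                        "vc": res.vc,
                    },
                    indent=2,
                )
            )
            record("associate", p_assoc)

            # agreement: diary vs derived total sleep time
            if len(diary):
                derived = day_table[["participant_id", "day_index", "total_sleep_time"]].copy()
                derived["derived_tst_min"] = derived["total_sleep_time"] * 60.0
                pairs = diary.merge(derived, on=["participant_id", "day_index"])
                ba = agr.bland_altman(
                    pairs["total_sleep_min"], pairs["derived_tst_min"], trait="total_sleep_time"
                )
                p_agr = out / "agreement.json"
                p_agr.write_text(json.dumps(vars(ba), indent=2))
                record("agree", p_agr)

            manifest.warnings = sorted({str(w.message) for w in caught})
    except Exception as e:  # abort with failure point recorded
        manifest.failure = f"{type(e).__name__}: {e}"
        manifest.finished = datetime.now(timezone.utc).isoformat()
        (out / "manifest.json").write_text(manifest.to_json())
        raise
    manifest.finished = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
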