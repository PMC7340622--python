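"""Pipeline orchestration: run stages in dependency order, write outputs,
and record a manifest sufficient to reproduce the run byte-for-byte."""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PIPELINE_STAGES, ConfigurationError, ScenarioConfig
from .effects import fit_diet_effect
from .sensitivity import nonadherence_sweep, tail_exclusion_comparison
from .simulate import sample_cohort, write_cohort, read_cohort, COLUMN_DICTIONARY
from .sweep import sequential_exclusion
from .tables import build_baseline_table, render_baseline_table
from .ue import add_ue_columns

__all__ = ["RunManifest", "run_pipeline", "COMMANDS"]

COMMANDS = ("simulate", "ue", "sweep", "table1", "sensitivity", "full")


@dataclass
class RunManifest:
    command: str
    seed: int
    config: dict
    child_seeds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def run_pipeline(
    command: str,
    config: ScenarioConfig | str | Path | None = None,
    seed: int | None = None,
    out_dir: str | Path = "exclusim-run",
    replicates: int = 100,
    per_protocol: bool = False,
    overwrite: bool = False,
    make_plots: bool = True,
) -> RunManifest:
    """Execute one pipeline stage (or ``'full'``) and write its outputs.

    Stages run in dependency order: a ``sweep`` or ``table1`` request first
    simulates and assigns UE if no cohort file exists in *out_dir*.  Prior
    stage outputs are reused only when present and never overwritten unless
    *overwrite* is set.
    """
    if command not in COMMANDS:
        raise ConfigurationError(f"unknown command {command!r}; choose from {COMMANDS}")
    if config is None:
        config = ScenarioConfig()
    elif not isinstance(config, ScenarioConfig):
        config = ScenarioConfig.from_file(config)
    if seed is not None:
        config = config.model_copy(update=dict(seed=int(seed)))
    config = config.validated()

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command, seed=config.seed,
        config=config.model_dump(mode="json"), started=_now(),
    )
    manifest.child_seeds = {
        stage: int(config.child_seed(stage).generate_state(1)[0])
        for stage in PIPELINE_STAGES
    }

    def _target(name: str) -> Path:
        p = out / name
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace it")
        return p

    cohort_path = out / "cohort.csv"
    cohort = None

    def _need_cohort() -> pd.DataFrame:
        nonlocal cohort
        if cohort is not None:
            return cohort
        if cohort_path.exists() and not overwrite:
            cohort = read_cohort(cohort_path)
        else:
            cohort = sample_cohort(config)
            write_cohort(cohort, _target("cohort.csv"))
            manifest.outputs.append(str(cohort_path))
        return cohort

    def _need_ue() -> pd.DataFrame:
        nonlocal cohort
        cohort = _need_cohort()
        if "ue" not in cohort.columns:
            cohort = add_ue_columns(cohort, config)
            p = _target("cohort_ue.csv")
            write_cohort(cohort, p)
            manifest.outputs.append(str(p))
        return cohort

    if command in ("simulate", "full"):
        _need_cohort()
        p = _target("column_dictionary.json")
        p.write_text(json.dumps(COLUMN_DICTIONARY, indent=2) + "\n")
        manifest.outputs.append(str(p))

    if command in ("ue", "full"):
        _need_ue()

    if command in ("table1", "full"):
        df = _need_cohort()
        if "ue_group" not in df.columns:
            if command == "table1" and cohort_path.exists() and not overwrite:
                raise ConfigurationError(
                    "cohort.csv lacks the ue_group column: run the 'ue' stage first"
                )
            df = _need_ue()
        rows = build_baseline_table(df)
        table = render_baseline_table(rows)
        p = _target("baseline_table.csv")
        table.to_csv(p, index=False)
        manifest.outputs.append(str(p))
        p = _target("baseline_table.txt")
        p.write_text(table.to_string(index=False) + "\n")
        manifest.outputs.append(str(p))

    if command in ("sweep", "full"):
        df = _need_ue()
        res = sequential_exclusion(df, config, per_protocol=per_protocol)
        p = _target("sweep.csv"); res.to_csv(p); manifest.outputs.append(str(p))
        p = _target("sweep.json"); res.to_json(p); manifest.outputs.append(str(p))
        if make_plots:
            p = _target("attenuation.svg")
            res.plot(p)
            manifest.outputs.append(str(p))
        full_fit = fit_diet_effect(df, adjusted=True, config=config,
                                   per_protocol=per_protocol)
        tails = tail_exclusion_comparison(df, config)
        p = _target("sweep_summary.json")
        p.write_text(json.dumps({
            "full_cohort_adjusted": full_fit.to_dict(),
            "tail_exclusion": tails,
        }, indent=2) + "\n")
        manifest.outputs.append(str(p))

    if command in ("sensitivity", "full"):
        res = nonadherence_sweep(config, replicates=replicates)
        p = _target("sensitivity.json"); res.to_json(p); manifest.outputs.append(str(p))
        p = _target("sensitivity.csv"); res.to_csv(p); manifest.outputs.append(str(p))

    manifest.finished = _now()
    mpath = out / "manifest.json"
    manifest.write(mpath)
    return manifest
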