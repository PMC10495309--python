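"""Experiment orchestration: the condition grid at configurable scale.

The full study grid is 2 radionuclides x 5 cell geometries x 2 arrangements
x 2 internalization scenarios x 10 source-count levels = 400 simulation
setups, each run with 10 independent seeds (4000 damage simulations), and
each damage pattern repaired 10 times.  The desk profile runs the same
machinery on a reduced grid so a laptop-scale smoke run finishes in
minutes; the paper-scale grid sits behind an explicit profile flag.

Seeds are derived hierarchically (master -> condition -> level -> run ->
repair repetition) via ``numpy.random.SeedSequence`` so every artefact is
reproducible from the master seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .damage import DamageParams, simulate_run
from .fitting import DoseEffectDataset, DoseEffectFit, fit_dose_effect, select_model
from .geometry import build_cluster, get_geometry
from .repair import RepairParams, mean_post_repair
from .rbe import NoCrossoverError, RbeModel, crossover_dose, propagate_rbe_sigma, rbe_vs_dose_ac
from .sources import SOURCE_GRID, SourceCountGrid, SourcePlan

__all__ = [
    "RunConfig",
    "ResultBundle",
    "FixtureError",
    "run_pipeline",
    "load_fixture_tables",
    "fixture_rbe_summary",
]

log = logging.getLogger("rbesim")

_FIXTURE_SHA256 = {
    "geometries.csv": "dedb85ac828f5a890611e6c37a4dcd8dc51e51247a8e9903fda82e0dbcd5b6cf",
    "lu_fit_params.csv": "9542cb881c5ef086e0ab017ba6dd3d303d339bc4a23f3c36007cb650c12ed877",
    "ac_fit_params.csv": "ea37669d352d833b30a38701b541f0c3850fd85bb4d558f32b6986ba59b5a6d1",
}


class FixtureError(RuntimeError):
    """Raised when a packaged fixture fails its integrity check."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one pipeline run."""

    geometries: tuple[int, ...] = (1, 2, 3, 4, 5)
    arrangements: tuple[str, ...] = ("planar_2d", "lattice_3d")
    internalizations: tuple[str, ...] = ("internalized", "membrane_bound")
    radionuclides: tuple[str, ...] = ("Lu177", "Ac225")
    source_grid: SourceCountGrid = field(default_factory=SourceCountGrid)
    runs_per_condition: int = 10
    repair_repetitions: int = 10
    master_seed: int = 0
    damage_params: DamageParams = field(default_factory=DamageParams)
    repair_params: RepairParams = field(default_factory=RepairParams)
    outdir: str | None = None

    @staticmethod
    def desk(master_seed: int = 0, outdir: str | None = None) -> "RunConfig":
        """Reduced grid: one geometry/arrangement/scenario, fewer seeds."""
        return RunConfig(
            geometries=(1,),
            arrangements=("lattice_3d",),
            internalizations=("internalized",),
            source_grid=SourceCountGrid(
                lu_counts=(500, 1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5000),
                ac_counts=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
            ),
            runs_per_condition=3,
            repair_repetitions=3,
            master_seed=master_seed,
            outdir=outdir,
        )

    @staticmethod
    def paper(master_seed: int = 0, outdir: str | None = None) -> "RunConfig":
        """The full 400-setup grid (computationally heavy)."""
        return RunConfig(master_seed=master_seed, outdir=outdir)

    def conditions(self) -> Iterator[tuple[str, int, str, str]]:
        for nuc in self.radionuclides:
            for geom in self.geometries:
                for arr in self.arrangements:
                    for intern in self.internalizations:
                        yield nuc, geom, arr, intern

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "source_grid" in raw:
            raw["source_grid"] = SourceCountGrid(
                lu_counts=tuple(raw["source_grid"]["lu_counts"]),
                ac_counts=tuple(raw["source_grid"]["ac_counts"]),
            )
        for key, cls in (("damage_params", DamageParams), ("repair_params", RepairParams)):
            if key in raw:
                raw[key] = cls(**raw[key])
        for key in ("geometries", "arrangements", "internalizations", "radionuclides"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)


@dataclass
class ResultBundle:
    """All pipeline outputs plus the reproducibility manifest."""

    runs: pd.DataFrame  # one row per damage simulation
    fits: pd.DataFrame  # one row per (condition, stage)
    rbe_summary: pd.DataFrame  # one row per (geometry, arr, intern, stage)
    manifest: dict
    failures: list = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.runs.to_csv(out / "runs.csv", index=False, float_format="%.10g")
        self.fits.to_csv(out / "fits.csv", index=False, float_format="%.10g")
        self.rbe_summary.to_csv(out / "rbe_summary.csv", index=False, float_format="%.10g")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))


def _condition_seed(master: int, nuc: str, geom: int, arr: str, intern: str) -> np.random.SeedSequence:
    key = f"{nuc}|{geom}|{arr}|{intern}".encode()
    digest = int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
    return np.random.SeedSequence([master, digest])


def simulate_condition(
    config: RunConfig, nuc: str, geom: int, arr: str, intern: str
) -> pd.DataFrame:
    """All damage+repair runs for one condition; one row per damage run."""
    cluster = build_cluster(get_geometry(geom), arr, nuc)
    counts = config.source_grid.counts_for(nuc)
    repair_params = dataclasses.replace(
        config.repair_params, repetitions=config.repair_repetitions
    )
    cond_ss = _condition_seed(config.master_seed, nuc, geom, arr, intern)
    rows = []
    level_streams = cond_ss.spawn(len(counts))
    for level_idx, (n_src, level_ss) in enumerate(zip(counts, level_streams)):
        plan = SourcePlan(radionuclide=nuc, scenario=intern, n_per_cell=int(n_src))
        for run_idx, run_ss in enumerate(level_ss.spawn(config.runs_per_condition)):
            dmg_ss, rep_ss = run_ss.spawn(2)
            record = simulate_run(cluster, plan, config.damage_params,
                                  np.random.default_rng(dmg_ss))
            post_mean, post_sd = mean_post_repair(
                record, repair_params, np.random.default_rng(rep_ss)
            )
            rows.append(
                {
                    "radionuclide": nuc,
                    "geometry": geom,
                    "arrangement": arr,
                    "internalization": intern,
                    "n_sources_per_cell": n_src,
                    "level": level_idx,
                    "run": run_idx,
                    "dose_gy": record.dose_gy,
                    "n_dsb_initial": record.n_dsb,
                    "n_dsb_post_mean": post_mean,
                    "n_dsb_post_sd": post_sd,
                }
            )
    return pd.DataFrame(rows)


def fit_condition(runs: pd.DataFrame, nuc: str, geom: int, arr: str, intern: str) -> list[dict]:
    """Fit the initial and post-repair dose-effect curves of one condition."""
    sel = runs[
        (runs.radionuclide == nuc)
        & (runs.geometry == geom)
        & (runs.arrangement == arr)
        & (runs.internalization == intern)
    ]
    out = []
    for stage, col in (("initial", "n_dsb_initial"), ("post_repair", "n_dsb_post_mean")):
        model = select_model(nuc, stage)
        ds = DoseEffectDataset(
            dose_gy=sel.dose_gy.to_numpy(),
            n_dsb=sel[col].to_numpy(),
            radionuclide=nuc,
            geometry=geom,
            arrangement=arr,
            internalization=intern,
            stage=stage,
        )
        fit = fit_dose_effect(ds, model)
        out.append(
            {
                "radionuclide": nuc,
                "geometry": geom,
                "arrangement": arr,
                "internalization": intern,
                "stage": stage,
                "model": model,
                "b": fit.b,
                "b_sd": fit.b_sd,
                "a": fit.a,
                "a_sd": fit.a_sd,
                "r_squared": fit.r_squared,
                "n_points": len(ds),
            }
        )
    return out


def rbe_from_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """Pair the two emitters' fits per condition and evaluate the RBE summary."""
    rows = []
    keys = ["geometry", "arrangement", "internalization", "stage"]
    for key, grp in fits.groupby(keys):
        nucs = set(grp.radionuclide)
        if not {"Lu177", "Ac225"} <= nucs:
            continue
        lu = grp[grp.radionuclide == "Lu177"].iloc[0]
        ac = grp[grp.radionuclide == "Ac225"].iloc[0]
        m = RbeModel(
            b_ac=ac.b, b_lu=lu.b, a_lu=lu.a,
            b_ac_sd=ac.b_sd, b_lu_sd=lu.b_sd, a_lu_sd=lu.a_sd,
        )
        rbe0 = m.b_ac / m.b_lu
        sigma0 = propagate_rbe_sigma(m, 0.0, "dose_ac")
        rbe1 = rbe_vs_dose_ac(m, 1.0)
        try:
            cross, cross_sd = crossover_dose(m)
        except (NoCrossoverError, ValueError):
            cross, cross_sd = float("nan"), float("nan")
        rows.append(
            dict(
                zip(keys, key),
                rbe_at_0=rbe0,
                rbe_at_0_sigma=sigma0,
                rbe_at_1gy_ac=rbe1,
                crossover_gy=cross,
                crossover_gy_sigma=cross_sd,
            )
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Build clusters, simulate, repair, fit and derive RBE for the whole grid.

    A failed condition is logged and skipped; its absence is recorded in
    the bundle's ``failures`` list.
    """
    all_runs: list[pd.DataFrame] = []
    fit_rows: list[dict] = []
    failures: list[dict] = []
    for nuc, geom, arr, intern in config.conditions():
        t0 = time.perf_counter()
        try:
            runs = simulate_condition(config, nuc, geom, arr, intern)
            fit_rows.extend(fit_condition(runs, nuc, geom, arr, intern))
            all_runs.append(runs)
            log.info(
                "condition %s/g%d/%s/%s: %d runs in %.1fs",
                nuc, geom, arr, intern, len(runs), time.perf_counter() - t0,
            )
        except Exception as exc:  # pragma: no cover - defensive
            log.error("condition %s/g%d/%s/%s failed: %s", nuc, geom, arr, intern, exc)
            failures.append({"condition": (nuc, geom, arr, intern), "error": str(exc)})
    runs_df = pd.concat(all_runs, ignore_index=True) if all_runs else pd.DataFrame()
    fits_df = pd.DataFrame(fit_rows)
    rbe_df = rbe_from_fits(fits_df) if not fits_df.empty else pd.DataFrame()
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_conditions": len(list(config.conditions())),
        "n_failures": len(failures),
    }
    bundle = ResultBundle(
        runs=runs_df, fits=fits_df, rbe_summary=rbe_df, manifest=manifest, failures=failures
    )
    if config.outdir:
        bundle.write(config.outdir)
    return bundle


def _read_fixture(name: str) -> pd.DataFrame:
    path = resources.files("rbesim.data").joinpath(name)
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureError(f"fixture {name} checksum mismatch: {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_fixture_tables() -> pd.DataFrame:
    """Load the packaged reference fit-parameter tables for both emitters.

    Returns one long table keyed by (radionuclide, geometry, internalization,
    arrangement, stage) with columns b, b_sd, a, a_sd -- 20 conditions x 2
    stages per emitter.
    """
    lu = _read_fixture("lu_fit_params.csv")
    ac = _read_fixture("ac_fit_params.csv")
    if len(lu) != 20 or len(ac) != 20:
        raise FixtureError("fixture tables must each contain 20 condition rows")
    rows = []
    for _, r in lu.iterrows():
        base = dict(radionuclide="Lu177", geometry=int(r.geometry),
                    internalization=r.internalization, arrangement=r.arrangement)
        rows.append({**base, "stage": "initial", "b": r.b_init, "b_sd": r.b_init_sd,
                     "a": 0.0, "a_sd": 0.0})
        rows.append({**base, "stage": "post_repair", "b": r.b_repair, "b_sd": r.b_repair_sd,
                     "a": r.a_repair, "a_sd": r.a_repair_sd})
    for _, r in ac.iterrows():
        base = dict(radionuclide="Ac225", geometry=int(r.geometry),
                    internalization=r.internalization, arrangement=r.arrangement)
        rows.append({**base, "stage": "initial", "b": r.b_init, "b_sd": r.b_init_sd,
                     "a": 0.0, "a_sd": 0.0})
        rows.append({**base, "stage": "post_repair", "b": r.b_repair, "b_sd": r.b_repair_sd,
                     "a": 0.0, "a_sd": 0.0})
    return pd.DataFrame(rows)


def fixture_rbe_models(
    arrangement: str | None = None, stage: str | None = None
) -> dict[tuple[int, str, str, str], RbeModel]:
    """RbeModel per (geometry, internalization, arrangement, stage) from the fixtures."""
    table = load_fixture_tables()
    models: dict[tuple[int, str, str, str], RbeModel] = {}
    keys = ["geometry", "internalization", "arrangement", "stage"]
    for key, grp in table.groupby(keys):
        geom, intern, arr, stg = key
        if arrangement and arr != arrangement:
            continue
        if stage and stg != stage:
            continue
        lu = grp[grp.radionuclide == "Lu177"].iloc[0]
        ac = grp[grp.radionuclide == "Ac225"].iloc[0]
        models[(int(geom), intern, arr, stg)] = RbeModel(
            b_ac=ac.b, b_lu=lu.b, a_lu=lu.a,
            b_ac_sd=ac.b_sd, b_lu_sd=lu.b_sd, a_lu_sd=lu.a_sd,
        )
    return models


def fixture_rbe_summary() -> pd.DataFrame:
    """RBE summary evaluated directly from the packaged fit tables."""
    rows = []
    for (geom, intern, arr, stage), m in fixture_rbe_models().items():
        rbe0 = m.b_ac / m.b_lu
        sigma0 = propagate_rbe_sigma(m, 0.0, "dose_ac")
        try:
            cross, cross_sd = crossover_dose(m)
        except (NoCrossoverError, ValueError):
            cross, cross_sd = float("nan"), float("nan")
        rows.append(
            {
                "geometry": geom,
                "internalization": intern,
                "arrangement": arr,
                "stage": stage,
                "rbe_at_0": rbe0,
                "rbe_at_0_sigma": sigma0,
                "rbe_at_1gy_ac": rbe_vs_dose_ac(m, 1.0),
                "rbe_at_50gy_ac": rbe_vs_dose_ac(m, 50.0),
                "crossover_gy": cross,
                "crossover_gy_sigma": cross_sd,
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["stage", "arrangement", "geometry", "internalization"], ignore_index=True
    )
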