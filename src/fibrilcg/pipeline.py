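"""End-to-end pipeline: build -> mineralize -> equilibrate -> crosslink
-> pull -> analyze.

Cross-links are inserted *after* the first equilibration, and the
destructive tensile test runs on the cross-linked model.  Every stage
persists its artifact in the run's output directory together with a
frozen copy of the resolved configuration, so a run is reproducible
from its output directory alone.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np

from .analysis import MechanicsReport, analyze
from .build import build_fibril
from .config import RunConfig, dump_config
from .crosslink import insert_crosslinks
from .dynamics import equilibrate, run_tensile
from .mineral import mineralize
from .model import save_model
from .parameters import ForceField, default_forcefield, load_forcefield

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("fibrilcg.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, outdir: Path | None):
    """Decorator-free stage wrapper with timing and error tagging."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.error("stage %s: FAILED after %.1f s", name,
                          time.perf_counter() - self.t0)
                raise PipelineError(name, exc) from exc
            log.info("stage %s: done in %.1f s", name,
                     time.perf_counter() - self.t0)
            return False
    return _Ctx()


def run_pipeline(config: RunConfig, seed: int | None = None,
                 forcefield: ForceField | None = None,
                 persist: bool = True) -> MechanicsReport:
    """Execute the full protocol described by ``config``.

    ``seed`` overrides ``config.seed``; one master seed fans out into
    independent streams for equilibration, cross-link placement and the
    pull.
    """
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    seed_equil, seed_xlink, seed_pull = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3))

    if forcefield is None:
        forcefield = (load_forcefield(config.forcefield_file)
                      if config.forcefield_file else default_forcefield())
    outdir: Path | None = None
    if persist:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        frozen = dataclasses.replace(config, seed=master)
        dump_config(frozen, outdir / "config.yaml")

    with _stage("build", outdir):
        model = build_fibril(config.layout, strengthen_ends=True,
                             forcefield=forcefield)
        if persist:
            save_model(model, outdir / "model_built.txt")

    with _stage("mineralize", outdir):
        model = mineralize(model, config.mineral, forcefield)
        if persist:
            save_model(model, outdir / "model_mineralized.txt")

    with _stage("equilibrate", outdir):
        model = equilibrate(model, config.protocol, seed=seed_equil,
                            n_steps=config.equil_steps,
                            forcefield=forcefield)
        if persist:
            save_model(model, outdir / "model_equilibrated.txt")

    with _stage("crosslink", outdir):
        model = insert_crosslinks(
            model,
            dataclasses.replace(config.crosslinks, seed=seed_xlink),
            forcefield)
        if persist:
            save_model(model, outdir / "model_crosslinked.txt")

    with _stage("pull", outdir):
        traj = run_tensile(model, config.protocol, seed=seed_pull,
                           forcefield=forcefield)
        if persist:
            traj.save(outdir / "trajectory.h5")

    with _stage("analyze", outdir):
        report = analyze(traj, units=config.analysis.units,
                         floor_frac=config.analysis.floor_frac,
                         drop_frac=config.analysis.drop_frac)
        if persist:
            report.curve.to_frame().to_csv(outdir / "stress_strain.csv",
                                           index=False)
            report.breaks.to_csv(outdir / "broken_bonds.csv", index=False)
            report.gaps.to_csv(outdir / "gap_length.csv", index=False)
            (outdir / "report.json").write_text(
                json.dumps(report.scalars(), indent=2))
    return report
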