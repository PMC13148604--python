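"""End-to-end pipeline: normalize, run all selectors, filter, measure.

The report is a plain JSON-serializable dict that validates against the
pydantic model :class:`PipelineReport` (whose JSON schema is the published
report schema).  Given a fixed configuration the report is byte-identical
across reruns — the pipeline has no hidden state and records no timestamps.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

from pydantic import BaseModel

from . import __version__
from .config import RunConfig
from .imaging_core import FilterParams, Image2D, apply_paganin, normalize_flat
from .io import read_frame, write_frame
from .metrics import histogram_stats, line_profile, local_contrast_map
from .selection import (LogGrid, fuzzy_interval, select_l_corr, select_l_nps,
                        select_l_std)

__all__ = ["run_pipeline", "PipelineReport", "report_json_schema"]

logger = logging.getLogger("paganin_autotune")


class SelectorReport(BaseModel):
    l_selected: float
    criterion: str
    epsilon: Optional[float] = None
    r_hat: Optional[float] = None
    interval: Optional[list[float]] = None
    diagnostics: dict


class MetricsReport(BaseModel):
    histogram_separation: dict
    contrast_map_mean: dict
    profile_variance: dict


class PipelineReport(BaseModel):
    """Published schema of the pipeline's JSON report."""

    version: str
    config_hash: str
    seed: int
    selections: dict[str, SelectorReport]
    phi_at_l_nps: float
    metrics: MetricsReport


def report_json_schema() -> dict:
    return PipelineReport.model_json_schema()


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            logger.info("stage %-12s %.3f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("load")
def _load(config: RunConfig) -> tuple[Image2D, Image2D]:
    px = config.geometry.pixel_size
    frame = read_frame(config.frame, dataset=config.frame_dataset, pixel_size=px)
    flat = read_frame(config.flat, dataset=config.frame_dataset, pixel_size=px)
    return frame, flat


@_stage("normalize")
def _normalize(frame: Image2D, flat: Image2D) -> Image2D:
    return normalize_flat(frame, flat)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run the full selection workflow on one frame/flat pair.

    Returns the report dict; with ``write_outputs`` the filtered frames
    (TIFF), curve CSVs and the JSON report land in ``config.output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    sel = config.selector
    frame, flat = _load(config)
    f = _normalize(frame, flat)

    bounds = (sel.bounds_min, sel.bounds_max)
    grid = LogGrid.make(sel.grid_min, sel.grid_max, sel.grid_points,
                        sel.grid_subintervals)

    selections: dict = {}

    @_stage("select_nps")
    def _nps():
        res = select_l_nps(f, eps=sel.eps, r_hat=sel.r_hat, bounds=bounds,
                           n_rings=sel.n_rings, scheme=sel.split_scheme)
        res.interval = fuzzy_interval(f, eps=sel.eps, r_hat=sel.r_hat,
                                      delta_r=sel.delta_r, bounds=bounds,
                                      n_rings=sel.n_rings,
                                      scheme=sel.split_scheme,
                                      check_monotone=False)
        return res

    res_nps = _nps()
    selections["nps"] = res_nps

    @_stage("select_std")
    def _std():
        return select_l_std(f, grid, upper=res_nps.l_selected)

    @_stage("select_corr")
    def _corr():
        return select_l_corr(f, grid)

    selections["std"] = _std()
    selections["corr"] = _corr()

    @_stage("filter")
    def _filter() -> dict[str, Image2D]:
        out = {"l0": apply_paganin(f, FilterParams(0.0))}
        for name, res in selections.items():
            out[name] = apply_paganin(f, FilterParams(res.l_selected))
        return out

    filtered = _filter()

    @_stage("metrics")
    def _metrics() -> MetricsReport:
        import numpy as np

        hist, cv, pv = {}, {}, {}
        mid = f.shape[0] // 2
        block = min(config.contrast_block, min(f.shape))
        for name, img in filtered.items():
            hist[name] = histogram_stats(img)["separation"]
            cmap = local_contrast_map(img, block)
            cv[name] = (float(np.nanmean(cmap.values[cmap.mask]))
                        if cmap.mask.any() else None)
            prof, pmask = line_profile(img, mid)
            pv[name] = float(np.var(prof[pmask])) if pmask.any() else None
        return MetricsReport(histogram_separation=hist, contrast_map_mean=cv,
                             profile_variance=pv)

    report = PipelineReport(
        version=__version__,
        config_hash=config.content_hash(),
        seed=config.seed,
        selections={k: SelectorReport(**v.to_dict()) for k, v in selections.items()},
        phi_at_l_nps=float(res_nps.diagnostics["phi_at_selected"]),
        metrics=_metrics(),
    ).model_dump()

    if write_outputs:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, img in filtered.items():
            write_frame(img, outdir / f"filtered_{name}.tif")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
    return report
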