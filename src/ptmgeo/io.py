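"""Run configuration, delimited-table I/O and the end-to-end pipeline.

All outputs are plain delimited text (tab-separated, full double precision)
or JSON; every file written by the pipeline carries the configuration hash
and seed so that runs are reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SamplingBox
from .solver import ClassifierThresholds
from .geometry import (
    ConnectivityConfig,
    build_spanning_forest,
    estimate_visibility,
    summarize_components,
)
from ._batch import bistability_indicator
from .sampling import (
    MAIN15,
    LabelledSample,
    estimate_volume,
    ilr_sample,
    label_sample,
    vegas_run,
)
from . import analysis as _analysis

__all__ = [
    "RunConfig",
    "write_table",
    "read_table",
    "TableFormatError",
    "run_pipeline",
]

logger = logging.getLogger("ptmgeo")

_SIGMA_PRESETS = {
    "main15": MAIN15,
}


class TableFormatError(ValueError):
    """A delimited table failed to parse; carries the offending line."""

    def __init__(self, path, line_number, message):
        super().__init__(f"{path}:{line_number}: {message}")
        self.path = path
        self.line_number = line_number


def write_table(path, table: pd.DataFrame) -> None:
    """Write a delimited text table with full double precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    """Read a delimited text table; malformed rows raise TableFormatError."""
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            ncol = len(header.split("\t"))
            for ln, line in enumerate(fh, start=2):
                if line.strip() and len(line.rstrip("\n").split("\t")) != ncol:
                    raise TableFormatError(path, ln, "wrong number of fields")
    except OSError as exc:
        raise TableFormatError(path, 0, str(exc)) from exc
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


@dataclass
class RunConfig:
    """Serialisable configuration of one pipeline run."""

    mode: str = "weak"  # weak | strong
    exponent_p: int = 1
    sigma_grid: list = field(default_factory=lambda: list(MAIN15))
    zeta: float = 1.0
    lam_rule: str = "equal_sigma"  # equal-to-sigma; or "explicit"
    lam: float | None = None
    n_points: int = 10_000
    seed: int = 0
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    geometry: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    out_dir: str = "ptmgeo_out"
    run_vegas: bool = False
    vegas_sigma: float = 10.0
    vegas_iterations: int = 2
    vegas_points: int = 10_000
    visibility_pairs: int = 200
    visibility_sigma: float = 10.0

    @property
    def dimension(self) -> int:
        return 8 if self.mode == "weak" else 6

    @property
    def box(self) -> SamplingBox:
        return SamplingBox(exponent_p=self.exponent_p, dimension=self.dimension)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("thresholds"), dict):
            d["thresholds"] = ClassifierThresholds(**d["thresholds"])
        if isinstance(d.get("geometry"), dict):
            d["geometry"] = ConnectivityConfig(**d["geometry"])
        if isinstance(d.get("sigma_grid"), str):
            d["sigma_grid"] = list(_SIGMA_PRESETS[d["sigma_grid"]])
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def digest(self) -> str:
        """Content hash of the scientific configuration (output path aside)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute sample -> label -> volume (-> vegas -> connect -> visibility
    -> blink -> tradeoff) and write all outputs under ``config.out_dir``.

    Returns a summary dictionary (also written as summary.json).  Any stage
    failure raises :class:`PipelineError` tagged with the stage; outputs of
    completed stages are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = {"config_hash": config.digest(), "seed": config.seed}
    config.to_json(out / "config.json")
    summary: dict = {"tag": tag, "stages": {}}

    stage = "sample"
    try:
        points = ilr_sample(config.n_points, config.box, config.seed)
        cols = [f"log10_theta{i+1}" for i in range(points.shape[1])]
        tbl = pd.DataFrame(points, columns=cols)
        for key, val in tag.items():
            tbl.attrs[key] = val
        write_table(out / "points.tsv", tbl)
        summary["stages"][stage] = {"n_points": int(config.n_points)}

        stage = "label"
        lam = None if config.lam_rule == "equal_sigma" else config.lam
        sample = label_sample(
            points, config.sigma_grid, box=config.box, seed=config.seed,
            mode=config.mode, zeta=config.zeta,
            lam_rule=config.lam_rule if lam is None else "explicit",
            thresholds=config.thresholds,
        )
        lab_tbl = pd.DataFrame(
            {f"sigma_{s:g}": sample.labels[float(s)] for s in config.sigma_grid}
        )
        lab_tbl.insert(0, "point_id", np.arange(sample.n_points))
        write_table(out / "labels.tsv", lab_tbl)
        summary["stages"][stage] = {
            "nongeneric_tally": {str(k): v for k, v in
                                 sample.nongeneric_tally.items()},
        }

        stage = "volume"
        vols = []
        for s in config.sigma_grid:
            est = estimate_volume(sample, float(s))
            vols.append(
                {"sigma": float(s), "v_hat": est.v_hat, "percent": est.percent,
                 "ci_low": est.ci_low, "ci_high": est.ci_high, "n": est.n,
                 "n_bistable": est.n_bistable, "rule_of_three": est.degenerate}
            )
        write_table(out / "volumes.tsv", pd.DataFrame(vols))
        summary["stages"][stage] = {"estimates": vols}

        enriched = None
        if config.run_vegas:
            stage = "vegas"
            s0 = float(config.vegas_sigma)
            init = sample.bistable_points(s0)
            if init.shape[0] == 0:
                raise ValueError(f"no bistable points at sigma={s0} to seed VEGAS")
            ilr_frac = init.shape[0] / sample.n_points
            res = vegas_run(
                init, config.vegas_iterations, config.vegas_points, s0,
                config.seed + 1, mode=config.mode, ilr_fraction=ilr_frac,
                thresholds=config.thresholds,
            )
            enriched = res.bistable_points
            write_table(
                out / "vegas_bistable.tsv",
                pd.DataFrame(enriched,
                             columns=cols),
            )
            summary["stages"][stage] = {
                "n_sampled": res.n_sampled, "n_new_bistable": res.n_new_bistable,
                "enrichment": res.enrichment,
            }

        stage = "connect"
        s0 = float(config.visibility_sigma)
        have_s0 = s0 in sample.labels
        conn_pts = (
            enriched if enriched is not None
            else sample.bistable_points(s0) if have_s0
            else np.empty((0, points.shape[1]))
        )
        conn = {}
        if conn_pts.shape[0]:
            graph = build_spanning_forest(conn_pts, config.geometry.delta)
            comp = summarize_components(graph)
            edges = pd.DataFrame(graph.edges, columns=["i", "j"])
            write_table(out / "forest_edges.tsv", edges)
            write_table(
                out / "components.tsv",
                pd.DataFrame({"point_id": np.arange(graph.n_vertices),
                              "component": graph.component}),
            )
            conn = {
                "n_points": comp.n_points, "n_components": comp.n_components,
                "largest": comp.largest, "second_largest": comp.second_largest,
                "n_singletons": comp.n_singletons,
                "largest_share_percent": comp.largest_share,
            }
        summary["stages"][stage] = conn

        stage = "visibility"
        vis = {}
        bi_pts = (
            sample.bistable_points(s0) if have_s0
            else np.empty((0, points.shape[1]))
        )
        max_pairs = bi_pts.shape[0] * (bi_pts.shape[0] - 1) // 2
        if bi_pts.shape[0] >= 2 and config.visibility_pairs <= max_pairs:
            indicator = bistability_indicator(
                s0, mode=config.mode, zeta=config.zeta,
                thresholds=config.thresholds,
            )
            est = estimate_visibility(
                bi_pts, indicator, config.visibility_pairs, seed=config.seed + 2
            )
            vis = {"ratio": est.ratio, "k": est.k_subdivisions,
                   "n_pairs": est.n_pairs, "ci_low": est.ci_low,
                   "ci_high": est.ci_high}
        summary["stages"][stage] = vis

        stage = "blink"
        blink = _analysis.blinking_summary(sample)
        write_table(out / "blinking.tsv", blink.table)
        summary["stages"][stage] = {
            "total_blinking": int(blink.table["bp"].sum()),
            "disqualified": blink.n_disqualified,
        }

        stage = "tradeoff"
        trade = {}
        if config.mode == "weak":
            rows = []
            for s in config.sigma_grid:
                tb = _analysis.tradeoff_bound(sample, float(s))
                rows.append({"sigma": tb.sigma, "k_hat": tb.k_hat,
                             "n_bistable": tb.n_bistable})
            write_table(out / "tradeoff.tsv", pd.DataFrame(rows))
            trade = {"k_hat": {str(r["sigma"]): r["k_hat"] for r in rows}}
        summary["stages"][stage] = trade
    except Exception as exc:  # noqa: BLE001 - re-tagged with the stage
        raise PipelineError(stage, exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
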