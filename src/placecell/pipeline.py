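"""End-to-end seeded drivers for the open-field and track analyses.

Stage order (open field): speed threshold -> bin -> smooth -> divide ->
information -> position time-shift shuffle -> classify -> field detection.
Track sessions additionally serialize running into the eight directed paths
and evaluate two shuffle nulls (trialwise and session-wide frame shifts);
a cell is a track place cell only if significant under both.

All randomness flows from the config seed: each cell's shuffle generator is
seeded by (master seed, cell id), so per-cell results are stable under cell
subsetting.  Persisted outputs use fixed float formatting, making repeated
seeded runs byte-identical.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaSpec, open_field_arena
from .behavior import PathSegmentation, apply_speed_threshold, serialize_track_paths
from .config import AnalysisConfig
from .core import PlacecellError
from .fields import PlaceField, detect_place_fields, shuffle_bin_threshold
from .io import SessionBundle, write_manifest
from .maps import BinGrid, OccupancyMap, RateMap, compute_path_rate_maps
from .stats import (
    OpenFieldShuffler,
    ShuffleMode,
    ShuffleSpec,
    SpatialInfoResult,
    classify_place_cell,
    path_maps_information,
    shuffle_null,
)


def cell_rng(master_seed: int, cell_id: int) -> np.random.Generator:
    """Per-cell generator derived from the master seed and the cell id."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, cell_id)))


@dataclass
class CellResult:
    cell_id: int
    info: SpatialInfoResult
    rate_map: RateMap | None = None
    fields: list[PlaceField] | None = None
    # track mode: separate results per null
    info_trialwise: SpatialInfoResult | None = None
    info_session: SpatialInfoResult | None = None
    peak_location: tuple | None = None


@dataclass
class OpenFieldResults:
    occupancy: OccupancyMap
    cells: list[CellResult]
    config: AnalysisConfig

    @property
    def place_cell_ids(self) -> list[int]:
        return [c.cell_id for c in self.cells if c.info.is_place_cell]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": c.cell_id,
                    "information_bits": c.info.information_bits,
                    "percentile": c.info.percentile,
                    "is_place_cell": c.info.is_place_cell,
                    "undefined": c.info.undefined,
                    "n_fields": len(c.fields) if c.fields is not None else 0,
                    "n_shuffles": len(c.info.null_bits),
                }
                for c in self.cells
            ]
        )


@dataclass
class TrackResults:
    segmentation: PathSegmentation
    cells: list[CellResult]
    config: AnalysisConfig

    @property
    def place_cell_ids(self) -> list[int]:
        return [c.cell_id for c in self.cells if c.info.is_place_cell]

    def peak_sort_order(self) -> np.ndarray:
        """Place cells ordered by concatenated-path peak location (raster export)."""
        pcs = [c for c in self.cells if c.info.is_place_cell]
        peaks = [c.peak_location[0] for c in pcs]
        order = np.argsort(peaks, kind="stable")
        return np.array([pcs[i].cell_id for i in order])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": c.cell_id,
                    "information_bits": c.info.information_bits,
                    "percentile_trialwise": c.info_trialwise.percentile,
                    "percentile_session": c.info_session.percentile,
                    "is_place_cell": c.info.is_place_cell,
                    "undefined": c.info.undefined,
                }
                for c in self.cells
            ]
        )


def run_open_field(
    bundle: SessionBundle,
    config: AnalysisConfig,
    arena: ArenaSpec | None = None,
    out_dir: str | Path | None = None,
    detect_fields: bool = True,
) -> OpenFieldResults:
    """Open-field pipeline over all cells of a session."""
    if config.mode != "open_field":
        raise PlacecellError("config mode must be open_field")
    arena = arena or open_field_arena()
    traj = apply_speed_threshold(bundle.trajectory, config.speed_threshold_cm_s)
    grid = BinGrid.for_circle(arena, config.bin_size_cm)
    engine = OpenFieldShuffler(
        traj, grid, sigma_cm=config.sigma_cm, min_occupancy_s=config.min_occupancy_s
    )
    spec = ShuffleSpec(
        mode=ShuffleMode.POSITION_TIME_SHIFT,
        n_shuffles=config.n_shuffles,
        margin_s=config.shuffle_margin_s,
    )
    results: list[CellResult] = []
    for row, cid in zip(bundle.activity.values, bundle.activity.cell_ids):
        cid = int(cid)
        rate = engine.rate_map_for(row)
        rate_map = RateMap(grid=grid, rate=rate, occupancy_s=engine.sm_occ,
                           valid=engine.occupied)
        true_info = engine.information_for(row)
        rng = cell_rng(config.seed, cid)
        nulls, null_maps = engine.null_informations(
            row, spec, rng, collect_maps=detect_fields
        )
        info = classify_place_cell(true_info, nulls, config.significance)
        fields = None
        if detect_fields:
            fields = []
            if info.is_place_cell:
                thr = shuffle_bin_threshold(null_maps, grid=grid)
                fields = detect_place_fields(
                    rate_map, thr,
                    min_seed_bins=config.field_min_seed_bins,
                    peak_fraction=config.field_peak_fraction,
                    connectivity=config.field_connectivity,
                )
        results.append(CellResult(cell_id=cid, info=info, rate_map=rate_map,
                                  fields=fields))
    out = OpenFieldResults(occupancy=engine.occ, cells=results, config=config)
    if out_dir is not None:
        _persist_open_field(out, Path(out_dir))
    return out


def run_track(
    bundle: SessionBundle,
    config: AnalysisConfig,
    track: ArenaSpec,
    segmentation: PathSegmentation | None = None,
    out_dir: str | Path | None = None,
) -> TrackResults:
    """Track pipeline: serialization, per-path maps, both shuffle nulls."""
    if config.mode != "track":
        raise PlacecellError("config mode must be track")
    traj = apply_speed_threshold(bundle.trajectory, config.speed_threshold_cm_s)
    if segmentation is None:
        segmentation = serialize_track_paths(bundle.trajectory, track)
    if len(segmentation) == 0:
        raise PlacecellError("no traversals found in this session")
    results: list[CellResult] = []
    for row, cid in zip(bundle.activity.values, bundle.activity.cell_ids):
        cid = int(cid)
        maps = compute_path_rate_maps(
            row, traj, segmentation, track,
            bin_size_cm=config.bin_size_cm, sigma_cm=config.sigma_cm,
        )
        true_info = path_maps_information(maps)
        rng = cell_rng(config.seed, cid)
        shared = dict(
            trajectory=traj, segmentation=segmentation, track=track,
            sigma_cm=config.sigma_cm, bin_size_cm=config.bin_size_cm, rng=rng,
        )
        nulls_trial = shuffle_null(
            row, spec=ShuffleSpec(mode=ShuffleMode.TRIALWISE_FRAME_SHIFT,
                                  n_shuffles=config.n_shuffles), **shared)
        nulls_sess = shuffle_null(
            row, spec=ShuffleSpec(mode=ShuffleMode.SESSION_FRAME_SHIFT,
                                  n_shuffles=config.n_shuffles), **shared)
        res_trial = classify_place_cell(true_info, nulls_trial, config.significance)
        res_sess = classify_place_cell(true_info, nulls_sess, config.significance)
        combined = SpatialInfoResult(
            information_bits=res_trial.information_bits,
            null_bits=np.concatenate([nulls_trial, nulls_sess]),
            percentile=min(res_trial.percentile, res_sess.percentile),
            is_place_cell=res_trial.is_place_cell and res_sess.is_place_cell,
            undefined=res_trial.undefined or res_sess.undefined,
        )
        occ, rate, valid = maps.concatenated()
        peak_idx = int(np.argmax(np.where(valid, rate, -np.inf))) if valid.any() else -1
        results.append(
            CellResult(
                cell_id=cid, info=combined,
                info_trialwise=res_trial, info_session=res_sess,
                peak_location=(peak_idx,),
            )
        )
    out = TrackResults(segmentation=segmentation, cells=results, config=config)
    if out_dir is not None:
        _persist_track(out, Path(out_dir))
    return out


# ---------------------------------------------------------------------------
# Persistence (deterministic byte output)


def _persist_open_field(res: OpenFieldResults, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    res.summary().to_csv(out_dir / "place_cells.csv", index=False,
                         float_format="%.9g")
    rows = []
    for c in res.cells:
        if not c.fields:
            continue
        for k, f in enumerate(c.fields):
            cy, cx = f.peak_bin
            gx, gy = c.rate_map.grid.bin_centers()
            rows.append(
                {
                    "cell_id": c.cell_id, "field_id": k, "n_bins": f.n_bins,
                    "peak_rate": f.peak_rate,
                    "peak_x_cm": gx[cx], "peak_y_cm": gy[cy],
                }
            )
    pd.DataFrame(rows, columns=["cell_id", "field_id", "n_bins", "peak_rate",
                                "peak_x_cm", "peak_y_cm"]).to_csv(
        out_dir / "place_fields.csv", index=False, float_format="%.9g")
    maps = np.stack([c.rate_map.rate for c in res.cells]) if res.cells else np.empty((0,))
    np.savez(out_dir / "rate_maps.npz", rate_maps=maps,
             occupancy_s=res.occupancy.t, valid=res.occupancy.valid)
    write_manifest(out_dir / "manifest.json", {
        "mode": "open_field",
        "n_cells": len(res.cells),
        "n_place_cells": len(res.place_cell_ids),
        "seed": res.config.seed,
        "outputs": ["place_cells.csv", "place_fields.csv", "rate_maps.npz"],
    })


def _persist_track(res: TrackResults, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    res.summary().to_csv(out_dir / "place_cells.csv", index=False,
                         float_format="%.9g")
    np.savetxt(out_dir / "peak_sort_order.csv", res.peak_sort_order(),
               fmt="%d", header="cell_id", comments="")
    from .io import write_segmentation_csv

    write_segmentation_csv(out_dir / "segmentation.csv", res.segmentation)
    write_manifest(out_dir / "manifest.json", {
        "mode": "track",
        "n_cells": len(res.cells),
        "n_place_cells": len(res.place_cell_ids),
        "n_traversals": len(res.segmentation),
        "seed": res.config.seed,
        "outputs": ["place_cells.csv", "peak_sort_order.csv", "segmentation.csv"],
    })
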