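"""Readers and writers for the package's on-disk formats.

SWC for arbors (one node per line: id, type, x, y, z, radius, parent; soma
type 1, dendrite type 3), CSV for point patterns, puncta tables and
lamination profiles, and a small JSON schema for directional spike counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import Arbor, DirectionalResponseSet, LaminationProfile, PointPattern, PunctaSet, make_arbor


# ---------------------------------------------------------------------- SWC

def read_swc(path: str | Path) -> Arbor:
    """Read an SWC reconstruction; tolerates ``#`` comments and tab/space mix."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace("\t", " ").split()
        if len(parts) != 7:
            raise ParameterError(f"malformed SWC line: {line!r}")
        nid, ntype, x, y, z, r, parent = parts
        rows.append((int(nid), int(parent), float(x), float(y), float(z), float(r), int(ntype)))
    if not rows:
        raise ParameterError(f"no nodes found in {path}")
    return make_arbor(rows)


def write_swc(arbor: Arbor, path: str | Path) -> None:
    lines = ["# id type x y z radius parent"]
    for k in range(arbor.n_nodes):
        pid = -1 if arbor.parent_index[k] == -1 else int(arbor.ids[arbor.parent_index[k]])
        lines.append(
            f"{int(arbor.ids[k])} {int(arbor.node_type[k])} "
            f"{arbor.xyz[k, 0]:.6f} {arbor.xyz[k, 1]:.6f} {arbor.xyz[k, 2]:.6f} "
            f"{arbor.radius[k]:.6f} {pid}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------- point pattern

def read_points_csv(path: str | Path,
                    window: tuple[float, float, float, float] | None = None) -> PointPattern:
    """Read soma centers from a CSV with ``x_um, y_um`` columns.

    Without an explicit window the bounding box of the points is used.
    """
    df = pd.read_csv(path)
    pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if window is None:
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        window = (float(x0), float(y0), float(x1), float(y1))
    return PointPattern(pts, window)


def write_points_csv(pattern: PointPattern, path: str | Path) -> None:
    pd.DataFrame(pattern.points, columns=["x_um", "y_um"]).to_csv(path, index=False)


# ------------------------------------------------------------------- puncta

def read_puncta_csv(path: str | Path, soma_center, arbor_radial_extent: float) -> PunctaSet:
    df = pd.read_csv(path)
    return PunctaSet(
        df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        df["volume_um3"].to_numpy(dtype=float),
        np.asarray(soma_center, dtype=float),
        float(arbor_radial_extent),
    )


def write_puncta_csv(puncta: PunctaSet, path: str | Path) -> None:
    df = pd.DataFrame(puncta.xyz, columns=["x_um", "y_um", "z_um"])
    df["volume_um3"] = puncta.volumes
    df.to_csv(path, index=False)


# --------------------------------------------------------------- lamination

def read_lamination_csv(path: str | Path) -> LaminationProfile:
    df = pd.read_csv(path)
    return LaminationProfile(df["depth"].to_numpy(dtype=float),
                             df["intensity"].to_numpy(dtype=float))


def write_lamination_csv(profile: LaminationProfile, path: str | Path) -> None:
    pd.DataFrame({"depth": profile.depths, "intensity": profile.intensities}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------- responses

def read_responses_json(path: str | Path) -> DirectionalResponseSet:
    data = json.loads(Path(path).read_text())
    units = data["units"]
    truth = data.get("ground_truth_ds")
    return DirectionalResponseSet(
        directions_deg=np.asarray(data["directions_deg"], dtype=float),
        epoch_dur_s=float(data["epoch_dur_s"]),
        unit_ids=[u["unit_id"] for u in units],
        counts=[np.asarray(u["counts"], dtype=np.int64) for u in units],
        ground_truth_ds=[bool(t) for t in truth] if truth is not None else None,
    )


def write_responses_json(responses: DirectionalResponseSet, path: str | Path) -> None:
    payload: dict = {
        "directions_deg": [float(d) for d in responses.directions_deg],
        "epoch_dur_s": responses.epoch_dur_s,
        "units": [
            {"unit_id": uid, "counts": c.tolist()}
            for uid, c in zip(responses.unit_ids, responses.counts)
        ],
    }
    if responses.ground_truth_ds is not None:
        payload["ground_truth_ds"] = [bool(t) for t in responses.ground_truth_ds]
    Path(path).write_text(json.dumps(payload))
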