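"""Residue-pair backbone distances across per-frame atomic models.

Atomic models fitted into the density maps along a functional path are compared
frame by frame: for a residue pair, the carbon-alpha distance is measured in
every starting model fitted to that frame, the per-frame value is the mean over
starting models, and the error bar is the full scatter (minimum to maximum
across models, not a standard deviation).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomicModel",
    "Selection",
    "DistanceSeries",
    "read_model",
    "backbone_distance",
    "distance_series",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class Selection:
    """An atom address: chain id, residue number, atom name (default CA)."""

    chain: str
    resnum: int
    atom: str = "CA"


@dataclasses.dataclass
class AtomicModel:
    """Flat atom table of one fitted model."""

    atoms: pd.DataFrame  # chain, resnum, resname, atom, x, y, z
    source: str = ""

    def coordinates(self, sel: Selection) -> np.ndarray:
        hit = self.atoms[
            (self.atoms["chain"] == sel.chain)
            & (self.atoms["resnum"] == sel.resnum)
            & (self.atoms["atom"] == sel.atom)
        ]
        if len(hit) == 0:
            raise KeyError(
                f"atom {sel.atom} of {sel.chain}/{sel.resnum} not found in {self.source or 'model'}"
            )
        if len(hit) > 1:
            raise KeyError(
                f"selection {sel.chain}/{sel.resnum}/{sel.atom} is not unique"
            )
        return hit[["x", "y", "z"]].to_numpy(dtype=float)[0]


def read_model(path, source: str | None = None) -> AtomicModel:
    """Parse ATOM/HETATM records from a PDB file.

    Alternate locations are resolved by keeping the highest-occupancy
    conformer; ties go to altloc 'A'.  Duplicate (chain, residue, atom)
    addresses after altloc resolution raise an error naming the duplicate.
    """
    structure = gemmi.read_structure(str(path))
    rows = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    rows.append(
                        {
                            "chain": chain.name,
                            "resnum": residue.seqid.num,
                            "resname": residue.name,
                            "atom": atom.name,
                            "altloc": atom.altloc or "",
                            "occupancy": float(atom.occ),
                            "x": atom.pos.x,
                            "y": atom.pos.y,
                            "z": atom.pos.z,
                        }
                    )
        break  # first model only
    if not rows:
        raise ValueError(f"{path}: no ATOM records")
    df = pd.DataFrame(rows)
    if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
        raise ValueError(f"{path}: non-finite coordinates")

    def resolve(group: pd.DataFrame) -> pd.DataFrame:
        if len(group) == 1:
            return group
        alt = group[group["altloc"] != ""]
        if len(alt) != len(group) or alt["altloc"].duplicated().any():
            key = group.iloc[0]
            raise ValueError(
                f"{path}: duplicate atom {key['chain']}/{key['resnum']}/{key['atom']}"
            )
        best = alt["occupancy"].max()
        top = alt[alt["occupancy"] == best]
        if len(top) > 1:
            a = top[top["altloc"] == "A"]
            top = a if len(a) else top.iloc[:1]
        return top.iloc[:1]

    df = (
        df.groupby(["chain", "resnum", "atom"], group_keys=False, sort=False)[df.columns]
        .apply(resolve)
        .reset_index(drop=True)
    )
    return AtomicModel(atoms=df.drop(columns=["altloc", "occupancy"]),
                       source=source or str(path))


def backbone_distance(model: AtomicModel, sel_a: Selection, sel_b: Selection) -> float:
    """Euclidean distance in Angstrom between two uniquely addressed atoms."""
    a = model.coordinates(sel_a)
    b = model.coordinates(sel_b)
    return float(np.linalg.norm(a - b))


@dataclasses.dataclass
class DistanceSeries:
    """Per-frame mean distance and full-scatter (min, max) bars for one residue pair."""

    pair: tuple[Selection, Selection]
    frame: np.ndarray
    mean: np.ndarray
    lo: np.ndarray  # scatter bar = full (min, max), not a standard deviation
    hi: np.ndarray
    n_models: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "mean": self.mean,
                "min": self.lo,
                "max": self.hi,
                "n_models": self.n_models,
            }
        )


def distance_series(
    models: Mapping[int, Sequence[AtomicModel]] | Sequence[Sequence[AtomicModel]],
    pairs: Sequence[tuple[Selection, Selection]],
) -> list[DistanceSeries]:
    """Distance statistics per frame over multiple starting models.

    ``models`` maps frame index to the models fitted to that frame (one per
    starting model).  Per frame and pair, the distances across models are
    averaged; the scatter bar is their full (min, max) range.  Models missing a
    selection are skipped with a logged warning; a frame where no model
    resolves the pair is an error.
    """
    if not isinstance(models, Mapping):
        models = dict(enumerate(models))
    frames = sorted(models)
    out = []
    for pair in pairs:
        means, los, his, ns = [], [], [], []
        for f in frames:
            dists = []
            for m in models[f]:
                try:
                    dists.append(backbone_distance(m, *pair))
                except KeyError as err:
                    logger.warning("frame %s: skipping model %s (%s)", f, m.source, err)
            if not dists:
                raise ValueError(
                    f"frame {f}: no model resolves pair {pair[0]}-{pair[1]}"
                )
            means.append(float(np.mean(dists)))
            los.append(float(np.min(dists)))
            his.append(float(np.max(dists)))
            ns.append(len(dists))
        out.append(
            DistanceSeries(
                pair=tuple(pair),
                frame=np.array(frames),
                mean=np.array(means),
                lo=np.array(los),
                hi=np.array(his),
                n_models=np.array(ns),
            )
        )
    return out
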