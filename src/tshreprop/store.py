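"""Hierarchical trajectory-record store (HDF5 + JSON sidecar).

One group per trajectory (named after the member label), with datasets for
every per-step array of :class:`~tshreprop.propagator.TrajectoryRecord`
and attributes for scalar metadata.  A JSON sidecar carries the schema
version, the model identifier and the run configuration, and is checked on
load so records from a different model cannot silently be repropagated.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .propagator import HopEvent, TrajectoryRecord

__all__ = ["save_records", "load_records", "StoreError", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_ARRAYS = ("t", "R", "P", "active", "energies", "prop", "dipole", "coeffs",
           "ekin", "proj_forces")


class StoreError(RuntimeError):
    """Raised on unreadable, truncated or incompatible stores."""


def _label_key(label: tuple) -> str:
    g, a = label
    return f"g{g}" if a is None else f"g{g}_a{a}"


def save_records(
    path,
    records: dict[tuple, TrajectoryRecord],
    config: dict | None = None,
) -> None:
    """Write a record store and its JSON sidecar."""
    path = Path(path)
    model_ids = {rec.model_id for rec in records.values()}
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        for label, rec in records.items():
            grp = fh.create_group(_label_key(label))
            for name in _ARRAYS:
                grp.create_dataset(name, data=getattr(rec, name))
            hops = np.array(
                [[ev.step, ev.time, ev.source, ev.target, int(ev.accepted)]
                 for ev in rec.hops],
                dtype=float,
            ).reshape(-1, 5)
            grp.create_dataset("hops", data=hops)
            grp.attrs.update(
                valid=rec.valid,
                invalid_reason=rec.invalid_reason,
                model_id=rec.model_id,
                seed=-1 if rec.seed is None else rec.seed,
                dt_fs=rec.dt_fs,
                n_substeps=rec.n_substeps,
                decoherence_scheme=rec.decoherence_scheme,
                g=label[0],
                a=-1 if label[1] is None else label[1],
            )
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "model_ids": sorted(model_ids),
        "n_records": len(records),
        "labels": [list(map(lambda x: None if x is None else int(x), lb))
                   for lb in records],
        "config": config or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )


def load_records(path, expect_model_id: str | None = None) -> dict[tuple, TrajectoryRecord]:
    """Read a record store back into memory.

    Raises :class:`StoreError` on schema mismatch, unreadable files, or —
    when ``expect_model_id`` is given — records produced by a different
    model.
    """
    path = Path(path)
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise StoreError(f"cannot read record store {path}: {exc}") from exc
    records: dict[tuple, TrajectoryRecord] = {}
    with fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise StoreError(
                f"store schema version {version} != supported {SCHEMA_VERSION}"
            )
        for key in fh:
            grp = fh[key]
            mid = grp.attrs["model_id"]
            if expect_model_id is not None and mid != expect_model_id:
                raise StoreError(
                    f"record {key} was produced by model {mid!r}, "
                    f"expected {expect_model_id!r}; refusing to mix models"
                )
            hops = [
                HopEvent(int(s), float(t), int(src), int(tgt), bool(acc))
                for s, t, src, tgt, acc in grp["hops"][()]
            ]
            a = int(grp.attrs["a"])
            g = int(grp.attrs["g"])
            seed = int(grp.attrs["seed"])
            rec = TrajectoryRecord(
                **{name: grp[name][()] for name in _ARRAYS},
                hops=hops,
                valid=bool(grp.attrs["valid"]),
                invalid_reason=str(grp.attrs["invalid_reason"]),
                model_id=str(mid),
                seed=None if seed < 0 else seed,
                dt_fs=float(grp.attrs["dt_fs"]),
                n_substeps=int(grp.attrs["n_substeps"]),
                decoherence_scheme=str(grp.attrs["decoherence_scheme"]),
            )
            records[(g, None if a < 0 else a)] = rec
    return records
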