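"""Reading and writing cohorts, time courses and adjacency matrices.

Cohorts are stored as one HDF5 container (``cohort.h5``: a
groups/subjects/bands hierarchy) plus a ``covariates.csv`` table, or as a
directory of TSV matrices with a JSON manifest. Individual adjacency
matrices round-trip through header-labeled TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bands import BandDefinition
from .envconn import RegionTimecourseSet
from .synthgen import CohortDataset, Subject

__all__ = [
    "save_cohort",
    "load_cohort",
    "export_cohort_tsv",
    "write_timecourses_h5",
    "read_timecourses_h5",
    "write_adjacency_tsv",
    "read_adjacency_tsv",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_bands(h5: h5py.File, bands: list[BandDefinition]) -> None:
    grp = h5.create_group("bands")
    grp.create_dataset("name", data=np.array([b.name for b in bands], dtype=_STR))
    grp.create_dataset("low", data=np.array([b.low for b in bands]))
    grp.create_dataset("high", data=np.array([b.high for b in bands]))


def _read_bands(h5: h5py.File) -> list[BandDefinition]:
    grp = h5["bands"]
    names = [s.decode() if isinstance(s, bytes) else str(s) for s in grp["name"][()]]
    return [
        BandDefinition(n, float(lo), float(hi))
        for n, lo, hi in zip(names, grp["low"][()], grp["high"][()])
    ]


def save_cohort(cohort: CohortDataset, outdir: str | Path) -> Path:
    """Write ``cohort.h5`` and ``covariates.csv`` under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "cohort.h5"
    with h5py.File(path, "w") as h5:
        h5.create_dataset(
            "region_labels", data=np.array(cohort.region_labels, dtype=_STR)
        )
        _write_bands(h5, cohort.bands)
        if cohort.planted:
            pg = h5.create_group("planted")
            for g, part in cohort.planted.items():
                pg.create_dataset(g, data=np.asarray(part, dtype=int))
        groups = h5.create_group("groups")
        for g, subs in cohort.groups.items():
            gg = groups.create_group(g)
            for s in subs:
                sg = gg.create_group(s.subject_id)
                if s.adjacency is not None:
                    ag = sg.create_group("adjacency")
                    for band, A in s.adjacency.items():
                        ag.create_dataset(band, data=np.asarray(A, dtype=float))
                if s.timecourse is not None:
                    ds = sg.create_dataset("timecourse", data=s.timecourse.data)
                    ds.attrs["fs"] = s.timecourse.fs
    cohort.covariates.to_csv(outdir / "covariates.csv", index=False)
    return path


def load_cohort(path: str | Path) -> CohortDataset:
    """Load a cohort written by :func:`save_cohort`.

    *path* may be the directory or the ``cohort.h5`` file itself; the
    covariates table is read from the sibling ``covariates.csv`` when
    present.
    """
    path = Path(path)
    h5path = path / "cohort.h5" if path.is_dir() else path
    with h5py.File(h5path, "r") as h5:
        region_labels = [
            s.decode() if isinstance(s, bytes) else str(s) for s in h5["region_labels"][()]
        ]
        bands = _read_bands(h5)
        planted = {}
        if "planted" in h5:
            planted = {g: h5["planted"][g][()] for g in h5["planted"]}
        groups: dict[str, list[Subject]] = {}
        for g in sorted(h5["groups"]):
            subs = []
            for sid in sorted(h5["groups"][g]):
                sg = h5["groups"][g][sid]
                adjacency = None
                timecourse = None
                if "adjacency" in sg:
                    adjacency = {band: sg["adjacency"][band][()] for band in sg["adjacency"]}
                if "timecourse" in sg:
                    timecourse = RegionTimecourseSet(
                        sg["timecourse"][()],
                        fs=float(sg["timecourse"].attrs["fs"]),
                        region_labels=list(region_labels),
                    )
                subs.append(
                    Subject(subject_id=sid, group=g, adjacency=adjacency, timecourse=timecourse)
                )
            groups[g] = subs
    cov_path = h5path.parent / "covariates.csv"
    covariates = pd.read_csv(cov_path) if cov_path.exists() else pd.DataFrame()
    return CohortDataset(
        groups=groups,
        bands=bands,
        covariates=covariates,
        region_labels=region_labels,
        planted=planted,
    )


def write_adjacency_tsv(weights: np.ndarray, labels: list[str], path: str | Path) -> None:
    """Header-labeled symmetric adjacency matrix as TSV."""
    df = pd.DataFrame(np.asarray(weights, dtype=float), index=labels, columns=labels)
    df.to_csv(path, sep="\t")


def read_adjacency_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def export_cohort_tsv(cohort: CohortDataset, outdir: str | Path) -> Path:
    """Cohort as a directory of per-subject per-band TSV matrices + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "region_labels": cohort.region_labels,
        "bands": [{"name": b.name, "low": b.low, "high": b.high} for b in cohort.bands],
        "groups": {},
    }
    for g, subs in cohort.groups.items():
        manifest["groups"][g] = []
        for s in subs:
            entry = {"subject_id": s.subject_id, "files": {}}
            if s.adjacency is not None:
                for band, A in s.adjacency.items():
                    fname = f"{s.subject_id}_{band}.tsv"
                    write_adjacency_tsv(A, cohort.region_labels, outdir / fname)
                    entry["files"][band] = fname
            manifest["groups"][g].append(entry)
    cohort.covariates.to_csv(outdir / "covariates.csv", index=False)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def write_timecourses_h5(tc: RegionTimecourseSet, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("data", data=tc.data)
        ds.attrs["fs"] = tc.fs
        h5.create_dataset("region_labels", data=np.array(tc.region_labels, dtype=_STR))


def read_timecourses_h5(path: str | Path) -> RegionTimecourseSet:
    with h5py.File(path, "r") as h5:
        labels = [
            s.decode() if isinstance(s, bytes) else str(s) for s in h5["region_labels"][()]
        ]
        return RegionTimecourseSet(
            h5["data"][()], fs=float(h5["data"].attrs["fs"]), region_labels=labels
        )
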