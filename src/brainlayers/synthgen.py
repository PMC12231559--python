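"""Synthetic cohorts with planted multilayer community structure.

Stands in for a two-group resting-state MEG cohort so that every downstream
stage (connectivity, supra-adjacency assembly, community detection, group
statistics) is testable without any recording. Two generation modes:

* **adjacency mode** — per-band N×N link-weight matrices drawn around a
  planted block structure (:func:`generate_planted_layers`), fast enough for
  full pipeline sweeps;
* **time-course mode** — region signals whose band-limited amplitude
  envelopes carry a target correlation pattern
  (:func:`generate_envelope_timecourses`), for end-to-end tests of the
  envelope-correlation chain.

Defaults emulate the study design this generator replaces: two groups of 15
subjects over 20 nodes and 5 frequency layers; group A carries a 2-module
structure, group B a 3-module structure; covariates follow age ~ N(28, 6²)
years and, for group A, years of training ~ N(13.25, 5.04²) truncated at 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BandDefinition, get_bands
from .envconn import RegionTimecourseSet

__all__ = [
    "PlantedSpec",
    "Subject",
    "CohortDataset",
    "generate_planted_layers",
    "generate_envelope_timecourses",
    "generate_cohort",
    "default_group_partitions",
]

#: Default link-weight levels for planted structure, on the scale of
#: amplitude-envelope correlations.
DEFAULT_INTRA = 0.6
DEFAULT_INTER = 0.15
DEFAULT_NOISE_SD = 0.05


@dataclass
class PlantedSpec:
    """Planted block structure for one subject's layer stack.

    ``partition_per_layer`` is (n_layers, n_nodes) of community indices
    contiguous from 1 (a 1-D array is broadcast to all layers). Links within
    a community get ``intra_weight``, links across get ``inter_weight``, plus
    zero-mean truncated-Gaussian noise of scale ``noise_sd`` (negative draws
    are re-drawn so weights stay nonnegative).
    """

    n_nodes: int
    n_layers: int
    partition_per_layer: np.ndarray
    intra_weight: float = DEFAULT_INTRA
    inter_weight: float = DEFAULT_INTER
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_layers < 1:
            raise ValueError("need at least 1 layer")
        if not (self.intra_weight > self.inter_weight >= 0):
            raise ValueError("require intra_weight > inter_weight >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        p = np.asarray(self.partition_per_layer, dtype=int)
        if p.ndim == 1:
            p = np.tile(p, (self.n_layers, 1))
        if p.shape != (self.n_layers, self.n_nodes):
            raise ValueError(
                f"partition_per_layer shape {p.shape} does not match "
                f"({self.n_layers}, {self.n_nodes})"
            )
        labels = np.unique(p)
        if labels[0] != 1 or not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise ValueError("community indices must be contiguous from 1")
        self.partition_per_layer = p


def generate_planted_layers(spec: PlantedSpec) -> list[np.ndarray]:
    """Draw one symmetric zero-diagonal N×N matrix per layer around the
    planted block structure. Reproducible given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    ii, jj = np.triu_indices(n, k=1)
    layers = []
    for l in range(spec.n_layers):
        lab = spec.partition_per_layer[l]
        base = np.where(lab[ii] == lab[jj], spec.intra_weight, spec.inter_weight)
        w = base.copy()
        if spec.noise_sd > 0:
            w = base + rng.normal(0.0, spec.noise_sd, size=base.size)
            for _ in range(1000):
                bad = w < 0
                if not bad.any():
                    break
                w[bad] = base[bad] + rng.normal(0.0, spec.noise_sd, size=int(bad.sum()))
            w = np.maximum(w, 0.0)
        A = np.zeros((n, n))
        A[ii, jj] = w
        A = A + A.T
        layers.append(A)
    return layers


# ---------------------------------------------------------------------------
# envelope time courses
# ---------------------------------------------------------------------------

def _nearest_corr_factor(R: np.ndarray) -> np.ndarray:
    """Factor L with L Lᵀ ≈ R after clipping negative eigenvalues."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 1e-10, None)
    L = vecs * np.sqrt(vals)
    # renormalize rows so the implied variances stay 1
    norms = np.linalg.norm(L, axis=1)
    return L / norms[:, None]




def generate_envelope_timecourses(
    n_regions: int,
    duration: float,
    fs: float,
    bands: list[BandDefinition] | str | None = "default",
    coupling_per_band: dict[str, np.ndarray] | None = None,
    seed: int | None = None,
    modulator_depth: float = 0.3,
    noise_amp: float = 0.02,
) -> RegionTimecourseSet:
    """Region signals whose band envelopes approximate target correlations.

    Per band, each region carries a narrowband tone (distinct frequency
    within the band, random phase) modulated by a slow (< 1 Hz) positive
    amplitude process, ``1 + depth·z`` rectified at a small floor, where the
    Gaussian slow processes z are empirically whitened and then mixed to the
    target correlation matrix — so the *envelope* correlations match
    ``coupling_per_band`` (band name → N×N symmetric target with entries in
    [−1, 1]; missing bands mean no coupling) up to the rare rectification.
    The full signal is the sum across bands plus broadband noise.
    """
    band_list = get_bands(bands)
    if fs < 2 * max(b.high for b in band_list):
        raise ValueError("fs must be at least twice the highest band edge")
    if duration < 60:
        raise ValueError("need at least 60 s for stable envelope correlations")
    coupling_per_band = coupling_per_band or {}
    for name, R in coupling_per_band.items():
        R = np.asarray(R, dtype=float)
        if R.shape != (n_regions, n_regions) or not np.allclose(R, R.T, atol=1e-10):
            raise ValueError(f"target pattern for band {name!r} must be symmetric N×N")
        if np.abs(R).max() > 1 + 1e-12:
            raise ValueError(f"target pattern for band {name!r} has |values| > 1")

    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * fs))
    t = np.arange(n_samp) / fs
    # modulator band < 1 Hz; the wider the band, the more effective samples a
    # finite recording carries, hence the tighter the measured correlations
    sos_slow = sps.butter(4, 0.8 / (fs / 2), btype="lowpass", output="sos")
    data = np.zeros((n_regions, n_samp))

    for band in band_list:
        R = np.asarray(coupling_per_band.get(band.name, np.eye(n_regions)), dtype=float)
        P = R - np.diag(np.diag(R)) + np.eye(n_regions)
        L = _nearest_corr_factor(P)
        g = rng.standard_normal((n_regions, n_samp))
        g = sps.sosfiltfilt(sos_slow, g, axis=1)
        g = g - g.mean(axis=1, keepdims=True)
        # empirical whitening: the mixed processes then carry the target
        # correlation exactly in sample, not only in expectation, which keeps
        # measured envelope correlations close to target at finite duration
        g = np.linalg.solve(np.linalg.cholesky(g @ g.T / n_samp), g)
        z = L @ g
        env = np.maximum(1.0 + modulator_depth * z, 0.02)
        # carriers sit in the middle of the band so modulation sidebands are
        # not clipped by the analysis band-pass (which distorts envelopes)
        margin = 0.3 * (band.high - band.low)
        freqs = np.linspace(band.low + margin, band.high - margin, n_regions)
        phases = rng.uniform(0, 2 * np.pi, size=n_regions)
        carriers = np.cos(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
        data += env * carriers

    data += noise_amp * rng.standard_normal(data.shape)
    return RegionTimecourseSet(data, fs=fs)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    """One subject: per-band adjacency matrices and/or a region time course."""

    subject_id: str
    group: str
    adjacency: dict[str, np.ndarray] | None = None
    timecourse: RegionTimecourseSet | None = None


@dataclass
class CohortDataset:
    """Two labeled groups of subjects sharing a node set and band set."""

    groups: dict[str, list[Subject]]
    bands: list[BandDefinition]
    covariates: pd.DataFrame
    region_labels: list[str]
    planted: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.groups) != 2 or any(len(v) == 0 for v in self.groups.values()):
            raise ValueError("cohort needs exactly two nonempty groups")
        n = len(self.region_labels)
        for subs in self.groups.values():
            for s in subs:
                if s.adjacency is not None:
                    for name, A in s.adjacency.items():
                        A = np.asarray(A)
                        if A.shape != (n, n):
                            raise ValueError(f"{s.subject_id}/{name}: wrong shape")
                        if not np.allclose(A, A.T, atol=1e-10) or np.abs(np.diag(A)).max() > 1e-12:
                            raise ValueError(
                                f"{s.subject_id}/{name}: adjacency must be symmetric, zero diagonal"
                            )

    @property
    def group_labels(self) -> list[str]:
        return list(self.groups)

    @property
    def n_nodes(self) -> int:
        return len(self.region_labels)

    def subjects(self) -> list[Subject]:
        return [s for subs in self.groups.values() for s in subs]

    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]


def default_group_partitions(n_nodes: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Planted node partitions: 2 equal-ish modules (group A) and 3 (group B)."""
    a = np.ones(n_nodes, dtype=int)
    a[n_nodes // 2 :] = 2
    sizes = [n_nodes // 3 + (1 if r < n_nodes % 3 else 0) for r in range(3)]
    b = np.concatenate([np.full(s, k + 1) for k, s in enumerate(sizes)])
    return a, b


def generate_cohort(
    n_per_group: int = 15,
    group_specs: tuple[PlantedSpec, PlantedSpec] | None = None,
    connectivity_offset: float = 0.0,
    seed: int | None = None,
    n_nodes: int = 20,
    n_layers: int = 5,
    noise_sd: float = DEFAULT_NOISE_SD,
    intra_weight: float = DEFAULT_INTRA,
    inter_weight: float = DEFAULT_INTER,
    bands: list[BandDefinition] | str | None = "default",
    group_labels: tuple[str, str] = ("A", "B"),
    mode: str = "adjacency",
    duration: float = 300.0,
    fs: float = 100.0,
) -> CohortDataset:
    """Simulate a two-group cohort with planted community structure.

    Group A subjects are drawn around a 2-module planted structure and group
    B around a 3-module structure (identical across layers), unless explicit
    ``group_specs`` override them. ``connectivity_offset`` is added uniformly
    to all of group A's link weights — a mean-connectivity confound that the
    SVD normalization is meant to remove. Covariates: age ~ N(28, 6²); years
    of training ~ N(13.25, 5.04²) truncated at ≥ 5 for group A and 0 for
    group B; age_started = age − years_experience for group A.

    ``mode="adjacency"`` (default) stores per-band adjacency matrices drawn
    directly around the planted blocks; ``mode="timecourses"`` instead
    synthesizes region time courses whose band envelopes target the planted
    block correlations (slower; intended for end-to-end tests of the
    envelope-correlation chain).
    """
    if mode not in ("adjacency", "timecourses"):
        raise ValueError("mode must be 'adjacency' or 'timecourses'")
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    band_list = get_bands(bands)
    if len(band_list) != n_layers:
        band_list = [
            BandDefinition(f"band{k + 1}", 1.0 + 2.0 * k, 2.0 + 2.0 * k) for k in range(n_layers)
        ]
    if group_specs is None:
        part_a, part_b = default_group_partitions(n_nodes)
        specs = {
            group_labels[0]: PlantedSpec(
                n_nodes, n_layers, part_a, intra_weight, inter_weight, noise_sd
            ),
            group_labels[1]: PlantedSpec(
                n_nodes, n_layers, part_b, intra_weight, inter_weight, noise_sd
            ),
        }
    else:
        specs = dict(zip(group_labels, group_specs))
        n_nodes = specs[group_labels[0]].n_nodes
        n_layers = specs[group_labels[0]].n_layers

    ss = np.random.SeedSequence(seed)
    cov_rng = np.random.default_rng(ss.spawn(1)[0])
    region_labels = [f"region_{i + 1:02d}" for i in range(n_nodes)]

    groups: dict[str, list[Subject]] = {g: [] for g in group_labels}
    cov_rows = []
    for gi, g in enumerate(group_labels):
        spec = specs[g]
        subj_seeds = ss.spawn(n_per_group)
        for k in range(n_per_group):
            sid = f"{g}{k + 1:02d}"
            sub_seed = int(subj_seeds[k].generate_state(1)[0]) & 0x7FFFFFFF
            sub_spec = PlantedSpec(
                spec.n_nodes,
                spec.n_layers,
                spec.partition_per_layer,
                spec.intra_weight,
                spec.inter_weight,
                spec.noise_sd,
                seed=sub_seed,
            )
            if mode == "adjacency":
                layers = generate_planted_layers(sub_spec)
                if gi == 0 and connectivity_offset != 0.0:
                    off = []
                    for A in layers:
                        B = A + connectivity_offset
                        np.fill_diagonal(B, 0.0)
                        off.append(np.maximum(B, 0.0))
                    layers = off
                adjacency = {band_list[l].name: layers[l] for l in range(spec.n_layers)}
                groups[g].append(Subject(subject_id=sid, group=g, adjacency=adjacency))
            else:
                targets = generate_planted_layers(sub_spec)
                coupling = {}
                for l in range(spec.n_layers):
                    T = np.clip(targets[l], 0.0, 0.95)
                    if gi == 0 and connectivity_offset != 0.0:
                        T = np.clip(T + connectivity_offset, 0.0, 0.95)
                        np.fill_diagonal(T, 0.0)
                    np.fill_diagonal(T, 1.0)
                    coupling[band_list[l].name] = T
                tc = generate_envelope_timecourses(
                    spec.n_nodes, duration, fs, bands=band_list,
                    coupling_per_band=coupling, seed=sub_seed,
                )
                tc.region_labels = list(region_labels)
                groups[g].append(Subject(subject_id=sid, group=g, timecourse=tc))

            age = float(cov_rng.normal(28.0, 6.0))
            if gi == 0:
                years = float(cov_rng.normal(13.25, 5.04))
                while years < 5.0:
                    years = float(cov_rng.normal(13.25, 5.04))
                years = min(years, max(age - 3.0, 5.0))
                started = age - years
            else:
                years, started = 0.0, np.nan
            cov_rows.append(
                {
                    "subject_id": sid,
                    "group": g,
                    "age": age,
                    "years_experience": years,
                    "age_started": started,
                }
            )

    covariates = pd.DataFrame(cov_rows)
    planted = {g: specs[g].partition_per_layer.copy() for g in group_labels}
    return CohortDataset(
        groups=groups,
        bands=band_list,
        covariates=covariates,
        region_labels=region_labels,
        planted=planted,
    )
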