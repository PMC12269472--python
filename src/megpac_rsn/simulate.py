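"""Synthetic source-space recordings with planted cross-frequency coupling.

The generator emulates the study design the pipeline is built for: four
recording conditions (first-OFF, first-ON, second-OFF, second-ON) drawn from a
pool of 20 subjects with per-condition exclusions (cohort sizes 18/18/17/19 by
default), three spatially disjoint resting-state networks, and per-vertex
phase-amplitude coupling between a low-frequency oscillation
(f_phi in [2, 30] Hz) and a high-gamma carrier (f_a in [80, 150] Hz).

Per-vertex signal model::

    x(t) = sin(2*pi*f_phi*t + theta_v)
           + kappa_eff * m_net(t) * g(t) * sin(2*pi*f_a*t + psi_v)
           + eps(t)

where g = (1 + sin(2*pi*f_phi*t + theta_v)) / 2 gates the gamma amplitude so
that it peaks at the *maxima* of the slow component (the property the megPAC
extrema sampling exploits), m_net(t) is a slow positive envelope (logistic of
standardized low-pass filtered noise) shared by all vertices of a network
within one recording, theta_v and psi_v are random per-vertex phases,
kappa_eff = kappa * condition-specific effect multiplier, and eps is white
Gaussian noise. Background vertices carry only the slow oscillation (at a
random frequency) plus noise: kappa = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .mesh import CorticalMesh, build_mesh

__all__ = [
    "CONDITIONS",
    "NetworkSpec",
    "EffectRegion",
    "SimulationConfig",
    "GroundTruth",
    "SourceRecording",
    "default_networks",
    "default_effect_regions",
    "simulate_recording",
    "generate_group",
    "condition_factors",
]

#: Condition labels: (recording session)-(medication state).
CONDITIONS = ("first-OFF", "first-ON", "second-OFF", "second-ON")

PHASE_FREQ_RANGE = (2.0, 30.0)
AMP_FREQ_RANGE = (80.0, 150.0)


def condition_factors(condition: str) -> tuple[str, str]:
    """Split a condition label into (session, medication) factor levels."""
    session, med = condition.split("-")
    return session, med


@dataclass(frozen=True)
class NetworkSpec:
    """One planted network: a vertex set sharing a slow envelope and
    a single (phase frequency, amplitude frequency) coupling pair."""

    name: str
    vertices: tuple[int, ...]
    phase_freq: float  # Hz, in [2, 30]
    amp_freq: float    # Hz, in [80, 150]


@dataclass(frozen=True)
class EffectRegion:
    """Vertex set whose coupling strength is multiplied per condition.

    ``kappa_scale`` scales the region's *baseline* coupling in every
    condition. The default effect region uses 0.5 so that even after the
    x1.5 condition multiplier the region stays below the network core:
    the coupling-strength maps are normalized to their maximum, so an
    effect inside the map's own maximum region would be absorbed by the
    0-1 rescaling instead of appearing at the planted vertices.
    """

    name: str
    vertices: tuple[int, ...]
    multipliers: dict  # condition -> float
    kappa_scale: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic group.

    Defaults reproduce the emulated study conditions: cohort sizes
    18/18/17/19 drawn from a 20-subject pool, 120 s recordings at 600 Hz,
    coupling strength kappa = 0.9, and a x1.5 coupling multiplier in a
    subregion of the first network for the second-session conditions.
    """

    n_subjects_per_condition: dict = field(
        default_factory=lambda: {
            "first-OFF": 18, "first-ON": 18, "second-OFF": 17, "second-ON": 19,
        }
    )
    mesh_spec: dict = field(
        default_factory=lambda: {"kind": "icosphere", "subdivisions": 2,
                                 "radius": 70.0}
    )
    networks: tuple[NetworkSpec, ...] | None = None  # None -> default_networks
    kappa: float = 0.9
    effect_regions: tuple[EffectRegion, ...] | None = None  # None -> default
    envelope_cutoff: float = 0.5  # Hz
    noise_sd: float = 0.5
    fs: float = 600.0             # Hz
    duration_s: float = 120.0
    seed: int = 0
    subject_pool: int = 20

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


#: Planted (phase_freq, amp_freq) pairs for the three default networks.
_DEFAULT_FREQS = {"SMN": (12.0, 90.0), "visual": (8.0, 110.0),
                  "frontal": (5.0, 130.0)}


#: Relative patch sizes (fraction of the mesh) for the default networks.
#: Distinct sizes keep the networks' correlation-matrix eigenvalues apart,
#: so the planted spatial modes are identifiable by SVD (equal-size,
#: equal-strength blocks would have degenerate principal modes that mix).
_DEFAULT_SIZES = {"SMN": 1 / 5, "visual": 1 / 7, "frontal": 1 / 9}


def default_networks(mesh: CorticalMesh) -> tuple[NetworkSpec, ...]:
    """Three disjoint patches around well-separated seed vertices.

    Patches hold the nearest n/5, n/7 and n/9 vertices to their seeds, so
    the networks cover roughly 45 % of the surface and the rest is
    background. Seeds come from farthest-point sampling, so the patches are
    far apart.
    """
    from .rsn import select_even_subset

    n = mesh.n_vertices
    seeds = select_even_subset(mesh, 3).subset_indices
    dists = mesh.vertex_distances()
    taken: set[int] = set()
    networks = []
    for name, seed_v in zip(_DEFAULT_FREQS, seeds):
        size = int(np.ceil(n * _DEFAULT_SIZES[name]))
        order = np.argsort(dists[seed_v])
        members = [int(v) for v in order if int(v) not in taken][:size]
        taken.update(members)
        fp, fa = _DEFAULT_FREQS[name]
        networks.append(NetworkSpec(name, tuple(sorted(members)), fp, fa))
    return tuple(networks)


def default_effect_regions(
    networks: tuple[NetworkSpec, ...], multiplier: float = 1.5
) -> tuple[EffectRegion, ...]:
    """x`multiplier` coupling in half of the first network for the
    second-session conditions (a planted session effect), at half the
    baseline coupling of the network core (see EffectRegion)."""
    first = networks[0]
    half = first.vertices[: max(1, len(first.vertices) // 2)]
    mult = {"second-OFF": multiplier, "second-ON": multiplier}
    return (EffectRegion(f"{first.name}-effect", tuple(half), mult,
                         kappa_scale=0.5),)


def resolve_config(
    config: SimulationConfig, mesh: CorticalMesh
) -> SimulationConfig:
    """Fill in mesh-dependent defaults (networks, effect regions) and validate."""
    cfg = config
    if cfg.networks is None:
        cfg = replace(cfg, networks=default_networks(mesh))
    if cfg.effect_regions is None:
        cfg = replace(cfg, effect_regions=default_effect_regions(cfg.networks))
    validate_config(cfg, mesh)
    return cfg


def validate_config(config: SimulationConfig, mesh: CorticalMesh) -> None:
    if config.networks is None:
        raise ValueError("config networks unresolved; call resolve_config")
    seen: set[int] = set()
    for net in config.networks:
        if not PHASE_FREQ_RANGE[0] <= net.phase_freq <= PHASE_FREQ_RANGE[1]:
            raise ValueError(
                f"network {net.name}: phase_freq {net.phase_freq} outside "
                f"{PHASE_FREQ_RANGE}"
            )
        if not AMP_FREQ_RANGE[0] <= net.amp_freq <= AMP_FREQ_RANGE[1]:
            raise ValueError(
                f"network {net.name}: amp_freq {net.amp_freq} outside "
                f"{AMP_FREQ_RANGE}"
            )
        vs = set(net.vertices)
        if vs & seen:
            raise ValueError("network vertex sets must be disjoint")
        if max(vs) >= mesh.n_vertices:
            raise ValueError(f"network {net.name}: vertex index out of range")
        seen |= vs
    if not 0.0 <= config.kappa <= 1.0:
        raise ValueError("kappa must be in [0, 1]")
    max_fa = max(net.amp_freq for net in config.networks)
    if config.fs <= 2 * max_fa:
        raise ValueError(
            f"fs = {config.fs} Hz aliases the {max_fa} Hz carrier "
            f"(need fs > {2 * max_fa})"
        )
    min_fp = min(net.phase_freq for net in config.networks)
    if config.duration_s * min_fp < 100:
        raise ValueError(
            f"duration {config.duration_s}s gives fewer than 100 cycles of "
            f"the slowest planted phase frequency ({min_fp} Hz)"
        )
    for cond, n in config.n_subjects_per_condition.items():
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        if not 1 <= n <= config.subject_pool:
            raise ValueError(f"cohort size {n} outside [1, pool]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure, for recovery checks downstream."""

    network_label: np.ndarray       # (V,) int; -1 = background
    network_names: tuple[str, ...]
    true_phase_freq: np.ndarray     # (V,) Hz
    true_amp_freq: np.ndarray       # (V,) Hz; NaN for background
    kappa_map: np.ndarray           # (V,) base coupling strength
    effect_multiplier: dict         # condition -> (V,) multiplier

    def network_map(self, name: str) -> np.ndarray:
        """Binary indicator map (1.0 inside the network) for template use."""
        idx = self.network_names.index(name)
        return (self.network_label == idx).astype(float)


@dataclass(frozen=True)
class SourceRecording:
    """One subject x condition source-space recording."""

    subject_id: str
    condition: str
    data: np.ndarray  # (n_vertices, n_samples)
    fs: float

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")


def _ground_truth(config: SimulationConfig, mesh: CorticalMesh) -> GroundTruth:
    n = mesh.n_vertices
    label = np.full(n, -1, int)
    fphi = np.zeros(n)
    fa = np.full(n, np.nan)
    kappa = np.zeros(n)
    names = tuple(net.name for net in config.networks)
    for i, net in enumerate(config.networks):
        vs = list(net.vertices)
        label[vs] = i
        fphi[vs] = net.phase_freq
        fa[vs] = net.amp_freq
        kappa[vs] = config.kappa
    # Background slow frequencies: deterministic function of the config seed
    # only (shared across subjects/conditions so GroundTruth is group-level).
    rng = np.random.default_rng([int(config.seed), 0xB0])
    bg = label < 0
    fphi[bg] = rng.uniform(*PHASE_FREQ_RANGE, size=int(bg.sum()))
    for region in config.effect_regions or ():
        kappa[list(region.vertices)] *= region.kappa_scale
    mult = {}
    for cond in CONDITIONS:
        m = np.ones(n)
        for region in config.effect_regions or ():
            m[list(region.vertices)] *= region.multipliers.get(cond, 1.0)
        mult[cond] = m
    return GroundTruth(label, names, fphi, fa, kappa, mult)


def _slow_envelope(rng: np.random.Generator, n: int, fs: float,
                   cutoff: float) -> np.ndarray:
    """Positive slow envelope in (0, 1): logistic of standardized low-passed
    white noise."""
    z = rng.standard_normal(n)
    sos = butter(4, cutoff, btype="low", fs=fs, output="sos")
    z = sosfiltfilt(sos, z)
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return 1.0 / (1.0 + np.exp(-z))


def simulate_recording(
    config: SimulationConfig,
    mesh: CorticalMesh,
    subject_id: str,
    condition: str,
    seed,
) -> tuple[SourceRecording, GroundTruth]:
    """Simulate one subject x condition recording; bit-deterministic in seed.

    `seed` may be an int or a sequence of ints (numpy SeedSequence entropy).
    """
    config = resolve_config(config, mesh)
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    gt = _ground_truth(config, mesh)
    rng = np.random.default_rng(seed)
    n_v, n_t = mesh.n_vertices, config.n_samples
    t = np.arange(n_t) / config.fs

    theta = rng.uniform(0, 2 * np.pi, n_v)
    psi = rng.uniform(0, 2 * np.pi, n_v)
    slow_phase = 2 * np.pi * gt.true_phase_freq[:, None] * t + theta[:, None]
    x = np.sin(slow_phase)

    mult = gt.effect_multiplier[condition]
    for i, net in enumerate(config.networks):
        vs = np.asarray(net.vertices, int)
        m = _slow_envelope(rng, n_t, config.fs, config.envelope_cutoff)
        gate = 0.5 * (1.0 + np.sin(slow_phase[vs]))
        carrier = np.sin(2 * np.pi * net.amp_freq * t + psi[vs, None])
        k_eff = (gt.kappa_map[vs] * mult[vs])[:, None]
        x[vs] += k_eff * m * gate * carrier

    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=(n_v, n_t))

    rec = SourceRecording(subject_id, condition, x, config.fs)
    return rec, gt


def generate_group(
    config: SimulationConfig, mesh: CorticalMesh | None = None
) -> tuple[dict, GroundTruth, CorticalMesh]:
    """Simulate all four condition cohorts from a shared subject pool.

    Returns ``(recordings, ground_truth, mesh)`` where ``recordings`` maps
    condition -> {subject_id: SourceRecording}. Per-condition cohorts drop a
    distinct random subset of the pool (emulating unequal usable groups, so
    downstream tests are unpaired by construction). All randomness derives
    from ``config.seed``; sub-seeds are per (subject, condition).
    """
    if mesh is None:
        mesh = build_mesh(config.mesh_spec)
    config = resolve_config(config, mesh)
    gt = _ground_truth(config, mesh)

    pool = [f"subj{i:02d}" for i in range(config.subject_pool)]
    rng = np.random.default_rng([int(config.seed), 0xD0])
    drops: list[frozenset] = []
    cohorts: dict[str, list[str]] = {}
    for cond in CONDITIONS:
        n_keep = config.n_subjects_per_condition.get(cond, 0)
        n_drop = config.subject_pool - n_keep
        for _ in range(1000):
            dropped = frozenset(
                rng.choice(config.subject_pool, size=n_drop, replace=False)
            )
            if n_drop == 0 or dropped not in drops:
                break
        drops.append(dropped)
        cohorts[cond] = [s for i, s in enumerate(pool) if i not in dropped]

    recordings: dict[str, dict] = {}
    for ci, cond in enumerate(CONDITIONS):
        recordings[cond] = {}
        for subj in cohorts[cond]:
            s_idx = pool.index(subj)
            sub_seed = [int(config.seed), 1, s_idx, ci]
            rec, _ = simulate_recording(config, mesh, subj, cond, sub_seed)
            recordings[cond][subj] = rec
    return recordings, gt, mesh
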