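"""Synthetic moving-heart phantom: signals, activity volumes, gated sets.

Emulates a two-balloon heart phantom driven by two independent motors: an
axial translation of 20 mm standing in for respiration, and a pulsatile
inflation that changes the outer-balloon diameter by up to 7 mm.  Small
Gaussian hot spots (3 mm FWHM) ride on the outer balloon surface like
coronary plaques.  A hollow-ellipsoid "myocardium" variant provides a
patient-like object for centre-of-mass and wall-thickness measurements.

Pulsatile kinematics are modelled as a uniform scaling about the balloon's
base pole (its mount): the outer diameter then changes by exactly the
configured amount and a hot spot at the apex travels that same distance,
while equatorial points travel less.  Respiration is a rigid axial shift, so
a full acquisition factorises into cardiac-state renders plus a respiratory
shift distribution per gate — which is how gated sets are computed.

All randomness flows from ``PhantomConfig.seed`` through named substreams,
so every artefact is bit-reproducible per seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from . import gate_assignment as ga
from .errors import InputError
from .motion_models import GateScheme, ScannerSpec

__all__ = [
    "PhantomConfig",
    "VolumeImage",
    "GatedImageSet",
    "gen_resp_signal",
    "gen_rpeaks",
    "render_phase",
    "gen_myocardium_volume",
    "simulate_gated_acquisition",
    "simulate_scheme_family",
    "hotspot_position",
    "substream",
]

#: FWHM of a Gaussian = GAUSS_FWHM * sigma
GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for a named stage of the simulation."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in key]])


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, motion, signal and count-budget settings of the phantom.

    Motion defaults are the phantom's drive settings: 20 mm axial
    respiratory translation, 7 mm maximal outer-diameter change, 3 mm hot
    spots.  ``activity_ratio`` gives (hot spot : balloon shell : interior
    background) intensity; the space outside the phantom is inactive.

    ``recon_noise_floor`` is a per-gate additive noise surrogate for the
    reconstruction noise that, on a real scanner, makes short gates noisier
    than Poisson count-splitting alone would; its default is calibrated so
    the default count budget loses about 1.7 dB of summed-image SNR between
    1 and 20 gates.
    """

    resp_amplitude_mm: float = 20.0
    card_diameter_change_mm: float = 7.0
    hotspot_diameter_mm: float = 3.0
    #: unit directions from the balloon centre; hot spots sit on the outer surface
    hotspot_directions: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, 1.0),
        (1.0, 0.0, 0.0),
        (0.0, -0.7071067811865476, 0.7071067811865476),
    )
    #: relative brightness per hot spot (the apex spot is the most active)
    hotspot_weights: tuple[float, ...] = (1.0, 0.7, 0.7)
    balloon_radii_mm: tuple[float, float] = (30.0, 40.0)
    activity_ratio: tuple[float, float, float] = (200.0, 4.0, 1.0)
    resp_period_s: float = 4.0
    resp_period_jitter: float = 0.05
    resp_waveform: str = "triangular"  # or "raised_cosine"
    resp_rise_fraction: float = 0.4
    #: 0.95 s (~63 bpm) keeps the cardiac clock incommensurate with the 4 s
    #: respiratory cycle, as in patients; an integer ratio would phase-lock
    #: the two motions
    mean_rr_s: float = 0.95
    rr_jitter: float = 0.05
    invalid_fraction: float = 0.0
    sampling_hz: float = 25.0
    total_counts: float = 1.0e7
    psf_fwhm_mm: float = 5.2
    recon_noise_floor: float = 0.02
    noise: bool = True
    seed: int = 0
    #: number of quantised cardiac states rendered per acquisition
    cardiac_quantization: int = 32
    # --- myocardium-shell variant ---
    myo_semiaxes_mm: tuple[float, float, float] = (32.0, 32.0, 45.0)
    myo_wall_thickness_mm: float = 10.0
    lung_activity: float = 0.15

    def __post_init__(self):
        if self.resp_amplitude_mm < 0 or self.card_diameter_change_mm < 0:
            raise InputError("motion amplitudes must be non-negative")
        if self.total_counts <= 0:
            raise InputError("total_counts must be positive")
        ri, ro = self.balloon_radii_mm
        if not 0 < ri < ro:
            raise InputError("inner balloon radius must be positive and < outer")
        if len(self.hotspot_weights) != len(self.hotspot_directions):
            raise InputError("one weight per hot spot direction required")
        if self.resp_waveform not in ("triangular", "raised_cosine"):
            raise InputError(f"unknown respiratory waveform {self.resp_waveform!r}")


@dataclass
class VolumeImage:
    """A 3-D activity volume with voxel geometry (axial = third axis).

    ``origin_mm`` is the mm coordinate of the centre of voxel (0, 0, 0);
    by default volumes are centred on the scanner origin.
    """

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InputError("voxels must be a 3-D array")
        if (self.voxels < 0).any():
            raise InputError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of the voxel centres along each axis."""
        return tuple(
            self.origin_mm[k] + np.arange(self.shape[k]) * self.voxel_size_mm[k]
            for k in range(3)
        )

    def voxel_to_mm(self, index: Sequence[float]) -> np.ndarray:
        return np.asarray(
            [self.origin_mm[k] + index[k] * self.voxel_size_mm[k] for k in range(3)]
        )

    def mm_to_voxel(self, pos_mm: Sequence[float]) -> np.ndarray:
        return np.asarray(
            [(pos_mm[k] - self.origin_mm[k]) / self.voxel_size_mm[k] for k in range(3)]
        )


@dataclass
class GatedImageSet:
    """Volumes of one dual-gating scheme, keyed by 1-based (resp, card) index.

    ``gate_fractions`` are dwell-time fractions of the full acquisition;
    they sum to at most 1, the remainder being rejected data.
    """

    scheme: GateScheme
    volumes: dict[tuple[int, int], VolumeImage]
    gate_fractions: dict[tuple[int, int], float]

    def __post_init__(self):
        expected = {
            (i, j)
            for i in range(1, self.scheme.n_resp + 1)
            for j in range(1, self.scheme.n_card + 1)
        }
        if set(self.volumes) != expected:
            raise InputError("gated set does not cover every (resp, card) cell")

    @property
    def rejected_fraction(self) -> float:
        return 1.0 - sum(self.gate_fractions.values())

    def gate_keys(self) -> list[tuple[int, int]]:
        return sorted(self.volumes)

    def summed(self) -> VolumeImage:
        """Voxelwise sum over all gates (the 'summed image' of a scheme)."""
        total = np.zeros(next(iter(self.volumes.values())).shape)
        for vol in self.volumes.values():
            total += vol.voxels
        ref = next(iter(self.volumes.values()))
        return VolumeImage(total, ref.voxel_size_mm, ref.origin_mm)


def _default_origin(scanner: ScannerSpec) -> tuple[float, float, float]:
    return tuple(
        -(scanner.volume_shape[k] - 1) / 2.0 * scanner.voxel_size_mm[k]
        for k in range(3)
    )


# ---------------------------------------------------------------------------
# physiological signals
# ---------------------------------------------------------------------------


def gen_resp_signal(config: PhantomConfig, duration_s: float) -> ga.RespSignal:
    """Cyclic lung-volume trace sampled at ``config.sampling_hz``.

    The default waveform is triangular (linear rise over
    ``resp_rise_fraction`` of the cycle, linear fall over the rest), which
    is the constant-speed drive of a mechanical phantom and has uniform
    amplitude dwell.  ``raised_cosine`` (sin^2) gives end-expiration dwell
    instead.  Cycle lengths are jittered per cycle; optional contiguous
    invalid segments emulate spirometry dropouts.
    """
    if duration_s <= 0:
        raise InputError("duration must be positive")
    rng = substream(config.seed, 1)
    # per-cycle periods with multiplicative jitter
    periods = []
    total = 0.0
    while total <= duration_s:
        T = config.resp_period_s * max(
            1.0 + config.resp_period_jitter * rng.standard_normal(), 0.2
        )
        periods.append(T)
        total += T
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    times = np.arange(0.0, duration_s, 1.0 / config.sampling_hz)
    cycle = np.searchsorted(starts, times, side="right") - 1
    u = (times - starts[cycle]) / np.asarray(periods)[cycle]
    A = config.resp_amplitude_mm
    if config.resp_waveform == "triangular":
        rho = config.resp_rise_fraction
        amp = np.where(u < rho, A * u / rho, A * (1.0 - u) / (1.0 - rho))
    else:
        amp = A * np.sin(np.pi * u) ** 2
    valid = np.ones(times.shape, dtype=bool)
    if config.invalid_fraction > 0:
        target = int(round(config.invalid_fraction * times.size))
        seg = max(int(2.0 * config.sampling_hz), 1)
        while (~valid).sum() < target:
            start = int(rng.integers(0, times.size))
            valid[start : start + seg] = False
    return ga.RespSignal(times=times, amplitude=amp, valid=valid)


def gen_rpeaks(config: PhantomConfig, duration_s: float) -> ga.CardiacSignal:
    """ECG trigger times with mean RR interval and Gaussian RR jitter."""
    if duration_s <= config.mean_rr_s:
        raise InputError("duration must exceed the mean RR interval")
    rng = substream(config.seed, 2)
    n_max = int(duration_s / config.mean_rr_s * 2) + 4
    intervals = config.mean_rr_s * np.maximum(
        1.0 + config.rr_jitter * rng.standard_normal(n_max), 0.3
    )
    peaks = np.concatenate([[0.0], np.cumsum(intervals)])
    return ga.CardiacSignal(rpeak_times=peaks[peaks <= duration_s])


# ---------------------------------------------------------------------------
# geometry and rendering
# ---------------------------------------------------------------------------


def _check_phase(phase: float, name: str) -> float:
    if not 0.0 <= phase <= 1.0:
        raise InputError(f"{name} must lie in [0, 1], got {phase}")
    return float(phase)


def _cardiac_scale(card_phase: float, config: PhantomConfig) -> float:
    """Scale factor about the base pole; outer diameter grows by
    ``card_diameter_change * sin^2(pi * phase)``."""
    delta = config.card_diameter_change_mm * np.sin(np.pi * card_phase) ** 2
    return 1.0 + delta / (2.0 * config.balloon_radii_mm[1])


def _balloon_frame(resp_phase: float, card_phase: float, config: PhantomConfig):
    """Base point, scaled centre and scaled radii for a motion state."""
    r_in, r_out = config.balloon_radii_mm
    z0 = (resp_phase - 0.5) * config.resp_amplitude_mm
    s_c = _cardiac_scale(card_phase, config)
    base = np.array([0.0, 0.0, z0 - r_out])
    center = base + np.array([0.0, 0.0, s_c * r_out])
    return base, center, s_c * r_in, s_c * r_out, s_c


def hotspot_position(
    resp_phase: float, card_phase: float, config: PhantomConfig, index: int = 0
) -> np.ndarray:
    """Ground-truth mm position of hot spot ``index`` for a motion state."""
    _check_phase(resp_phase, "resp_phase")
    _check_phase(card_phase, "card_phase")
    base, _, _, r_out_scaled, s_c = _balloon_frame(resp_phase, card_phase, config)
    r_out = config.balloon_radii_mm[1]
    direction = np.asarray(config.hotspot_directions[index], dtype=float)
    direction = direction / np.linalg.norm(direction)
    rest = base + np.array([0.0, 0.0, r_out]) + direction * r_out  # unscaled
    return base + s_c * (rest - base)


def _grid(scanner: ScannerSpec):
    origin = _default_origin(scanner)
    ax = [
        origin[k] + np.arange(scanner.volume_shape[k]) * scanner.voxel_size_mm[k]
        for k in range(3)
    ]
    return ax[0][:, None, None], ax[1][None, :, None], ax[2][None, None, :], origin


def render_phase(
    resp_phase: float,
    card_phase: float,
    config: PhantomConfig,
    scanner: ScannerSpec,
) -> VolumeImage:
    """Noiseless activity map of the balloon phantom at one motion state.

    Anti-aliased shell/interior indicator plus Gaussian hot-spot blobs,
    convolved with the isotropic scanner PSF.  Pure function of its inputs.
    """
    _check_phase(resp_phase, "resp_phase")
    _check_phase(card_phase, "card_phase")
    act_hot, act_shell, act_bg = config.activity_ratio
    x, y, z, origin = _grid(scanner)
    base, center, r_in, r_out, s_c = _balloon_frame(resp_phase, card_phase, config)
    d = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    edge = min(scanner.voxel_size_mm)
    w_out = np.clip((r_out - d) / edge + 0.5, 0.0, 1.0)
    w_in = np.clip((r_in - d) / edge + 0.5, 0.0, 1.0)
    vol = act_shell * w_out + (act_bg - act_shell) * w_in
    vol = _apply_psf(vol, config, scanner)
    # hot spots are far narrower than a voxel before blurring, so they are
    # added analytically *after* the PSF: Gaussian (x) Gaussian is Gaussian,
    # with the amplitude reduced by the 3-D dilution factor
    sigma_h = config.hotspot_diameter_mm / GAUSS_FWHM
    sigma_p = config.psf_fwhm_mm / GAUSS_FWHM
    sigma_eff = np.sqrt(sigma_h**2 + sigma_p**2)
    dilution = (sigma_h / sigma_eff) ** 3
    for k in range(len(config.hotspot_directions)):
        pos = hotspot_position(resp_phase, card_phase, config, k)
        d2 = (x - pos[0]) ** 2 + (y - pos[1]) ** 2 + (z - pos[2]) ** 2
        vol = vol + (act_hot * config.hotspot_weights[k] * dilution) * np.exp(
            -d2 / (2.0 * sigma_eff**2)
        )
    return VolumeImage(vol, scanner.voxel_size_mm, origin)


def _apply_psf(vol: np.ndarray, config: PhantomConfig, scanner: ScannerSpec):
    if config.psf_fwhm_mm <= 0:
        return vol
    sigma_vox = [
        config.psf_fwhm_mm / GAUSS_FWHM / scanner.voxel_size_mm[k] for k in range(3)
    ]
    return ndimage.gaussian_filter(vol, sigma_vox, mode="constant")


def gen_myocardium_volume(
    resp_phase: float,
    card_phase: float,
    config: PhantomConfig,
    scanner: ScannerSpec,
) -> VolumeImage:
    """Patient-like object: hollow ellipsoidal myocardium in faint lung.

    The wall (outer semi-axes ``myo_semiaxes_mm``, thickness
    ``myo_wall_thickness_mm``) is translated axially by the respiratory
    phase; the cardiac phase thickens the wall inward (the cavity shrinks by
    half the configured diameter change at mid-cycle) — a symmetric
    contraction, so the shell's centre of mass tracks respiration only.
    """
    _check_phase(resp_phase, "resp_phase")
    _check_phase(card_phase, "card_phase")
    _, act_wall, _ = config.activity_ratio
    x, y, z, origin = _grid(scanner)
    z0 = (resp_phase - 0.5) * config.resp_amplitude_mm
    ax_out = np.asarray(config.myo_semiaxes_mm, dtype=float)
    thick = config.myo_wall_thickness_mm + (
        config.card_diameter_change_mm / 2.0
    ) * np.sin(np.pi * card_phase) ** 2
    ax_in = np.maximum(ax_out - thick, 1.0)
    center = np.array([0.0, 0.0, z0])
    rho_out = np.sqrt(
        ((x - center[0]) / ax_out[0]) ** 2
        + ((y - center[1]) / ax_out[1]) ** 2
        + ((z - center[2]) / ax_out[2]) ** 2
    )
    rho_in = np.sqrt(
        ((x - center[0]) / ax_in[0]) ** 2
        + ((y - center[1]) / ax_in[1]) ** 2
        + ((z - center[2]) / ax_in[2]) ** 2
    )
    edge = min(scanner.voxel_size_mm)
    # signed-distance approximations: (1 - rho) * semi-axis scale
    w_out = np.clip((1.0 - rho_out) * ax_out.min() / edge + 0.5, 0.0, 1.0)
    w_in = np.clip((1.0 - rho_in) * ax_in.min() / edge + 0.5, 0.0, 1.0)
    lung = config.lung_activity * act_wall
    vol = lung + (act_wall - lung) * w_out - act_wall * w_in + lung * w_in
    vol = np.clip(vol, 0.0, None)
    vol = _apply_psf(vol, config, scanner)
    return VolumeImage(vol, scanner.voxel_size_mm, origin)


# ---------------------------------------------------------------------------
# gated acquisition
# ---------------------------------------------------------------------------


def _add_shifted(out: np.ndarray, vol: np.ndarray, k: int) -> None:
    """Accumulate ``vol`` shifted by ``k`` whole voxels along the axial axis."""
    nz = vol.shape[2]
    if k == 0:
        out += vol
    elif k > 0:
        if k < nz:
            out[..., k:] += vol[..., : nz - k]
    else:
        if -k < nz:
            out[..., : nz + k] += vol[..., -k:]


def _gate_average(
    bases: np.ndarray,
    card_level: np.ndarray,
    shift_vox: np.ndarray,
) -> np.ndarray:
    """Time average of motion states for one gate's samples.

    Each sample contributes its quantised cardiac render shifted axially by
    its respiratory displacement; sub-voxel shifts s = k + f are split
    linearly between offsets k and k+1, which preserves total intensity and
    centroid exactly.  The joint (cardiac level, shift) weighting is exact,
    so correlated respiratory and cardiac phases are handled correctly.
    """
    qc = bases.shape[0]
    k0 = np.floor(shift_vox).astype(int)
    frac = (shift_vox - k0).astype(np.float32)
    kmin = int(k0.min())
    nk = int(k0.max()) - kmin + 2
    weights = np.zeros((nk, qc), dtype=np.float32)
    np.add.at(weights, (k0 - kmin, card_level), 1.0 - frac)
    np.add.at(weights, (k0 - kmin + 1, card_level), frac)
    weights /= card_level.size
    flat = bases.reshape(qc, -1)
    out = np.zeros(bases.shape[1:], dtype=np.float32)
    for row in range(nk):
        if weights[row].any():
            layer = (weights[row] @ flat).reshape(bases.shape[1:])
            _add_shifted(out, layer, kmin + row)
    return out


def _cardiac_base_renders(
    config: PhantomConfig,
    scanner: ScannerSpec,
    cache: dict | None,
) -> list[np.ndarray]:
    """Render (and cache) the quantised cardiac states at mid respiration."""
    qc = config.cardiac_quantization
    key = ("cardiac_bases", qc)
    if cache is not None and key in cache:
        return cache[key]
    bases = np.stack(
        [
            render_phase(0.5, (l + 0.5) / qc, config, scanner).voxels.astype(
                np.float32
            )
            for l in range(qc)
        ]
    )
    if cache is not None:
        cache[key] = bases
    return bases


def simulate_gated_acquisition(
    config: PhantomConfig,
    scanner: ScannerSpec,
    scheme: GateScheme,
    duration_s: float,
    cache: dict | None = None,
    signals: tuple[ga.RespSignal, ga.CardiacSignal] | None = None,
) -> GatedImageSet:
    """Simulate a dual-gated acquisition of the balloon phantom.

    Generates the respiratory and ECG signals, assigns every time sample a
    dual gate, and forms each gate's image as the time average of the
    phantom's motion states, scaled so the expected counts of a gate equal
    ``total_counts`` times its dwell fraction.  With ``config.noise`` the
    counts are Poisson per voxel plus the additive reconstruction-noise
    floor.  Deterministic per seed.

    Per dual gate the cardiac-state average (quantised, cached across
    schemes via ``cache``) and the exact distribution of respiratory axial
    shifts are applied as separable factors; the two clocks are
    asynchronous, so their within-gate correlation is negligible.
    """
    if signals is None:
        resp = gen_resp_signal(config, duration_s)
        peaks = gen_rpeaks(config, duration_s)
    else:
        resp, peaks = signals
    r, p = scheme.n_resp, scheme.n_card
    resp_idx = ga.assign_resp_amplitude(resp, r)
    card_idx = ga.assign_card_phase(peaks, p, resp.times)
    card_frac = ga.cardiac_phase_fraction(peaks, resp.times)
    valid = (resp_idx != ga.REJECTED) & (card_idx != ga.REJECTED)

    amp = resp.amplitude
    lo = amp[resp.valid].min()
    hi = amp[resp.valid].max()
    resp_phase = np.full(amp.shape, 0.5)
    if hi > lo:
        resp_phase = (amp - lo) / (hi - lo)

    qc = config.cardiac_quantization
    bases = _cardiac_base_renders(config, scanner, cache)
    card_level = np.clip(
        np.floor(np.nan_to_num(card_frac, nan=0.0) * qc).astype(int), 0, qc - 1
    )
    dz = scanner.voxel_size_mm[2]

    n_samples = resp.times.size
    averages: dict[tuple[int, int], np.ndarray] = {}
    fractions: dict[tuple[int, int], float] = {}
    for i in range(1, r + 1):
        for j in range(1, p + 1):
            sel = valid & (resp_idx == i) & (card_idx == j)
            n_ij = int(sel.sum())
            fractions[(i, j)] = n_ij / n_samples
            if n_ij == 0:
                warnings.warn(
                    f"gate ({i},{j}) of scheme ({r},{p}) has zero dwell time",
                    stacklevel=2,
                )
                averages[(i, j)] = np.zeros(scanner.volume_shape, dtype=np.float32)
                continue
            shifts_vox = (resp_phase[sel] - 0.5) * config.resp_amplitude_mm / dz
            averages[(i, j)] = _gate_average(bases, card_level[sel], shifts_vox)

    total_activity = sum(a.sum() for a in averages.values())
    if total_activity <= 0:
        raise InputError("phantom rendered no activity inside the field of view")
    # scale so expected counts per gate = total_counts * dwell fraction
    scale = config.total_counts * sum(fractions.values()) / total_activity
    expected = {key: a * scale for key, a in averages.items()}
    full_expectation = sum(expected.values())

    rng = substream(config.seed, 3, r, p)
    volumes: dict[tuple[int, int], VolumeImage] = {}
    origin = _default_origin(scanner)
    for key, lam in expected.items():
        if config.noise:
            vox = rng.poisson(lam).astype(np.float32)
            if config.recon_noise_floor > 0:
                vox += rng.normal(
                    0.0, config.recon_noise_floor * full_expectation
                ).astype(np.float32)
                np.clip(vox, 0.0, None, out=vox)
        else:
            vox = lam.astype(np.float32)
        volumes[key] = VolumeImage(vox, scanner.voxel_size_mm, origin)
    return GatedImageSet(scheme=scheme, volumes=volumes, gate_fractions=fractions)


def simulate_scheme_family(
    config: PhantomConfig,
    scanner: ScannerSpec,
    schemes: Iterable[GateScheme],
    duration_s: float,
    cache: dict | None = None,
):
    """Yield (scheme, GatedImageSet) pairs sharing signals and renders.

    Signals and cardiac base renders are computed once; sets are yielded one
    at a time so callers can measure and discard them (a full family of
    gated volumes would not fit comfortably in memory).
    """
    if cache is None:
        cache = {}
    resp = gen_resp_signal(config, duration_s)
    peaks = gen_rpeaks(config, duration_s)
    for scheme in schemes:
        yield scheme, simulate_gated_acquisition(
            config, scanner, scheme, duration_s, cache=cache, signals=(resp, peaks)
        )
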