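"""Synthetic two-species antennal-lobe data with known ground truth.

Generates everything the analysis stages consume -- glomerular
fluorescence traces (optionally rendered as label-masked movies),
per-fly glomerular volumes, and four-choice trap counts -- with the
statistical structure the comparative analysis assumes:

* two species sharing a glomerular tuning matrix up to an additive,
  rectified per-(glomerulus, stimulus) shift of the odour code;
* mixture stimuli combined from their components by divisive
  normalization, spanning linear summation to suppression;
* a single multiplicative, log-scale response gain per fly whose spread
  differs between species (the asymmetric within-species variance that
  drives the within/between distance analysis);
* phasic-to-tonic response kernels (saturating exponential rise during
  the stimulus, exponential decay toward a tonic plateau afterwards);
* antennal-lobe volumes in which one species' AL is globally 50 %
  larger, with a designed set of glomeruli shifted in relative volume;
* multinomially distributed four-choice trap counts.

All randomness flows from one root seed: each generator draws from a
named substream (``stream(seed, label)``), so modules are reproducible
in isolation and identical configurations give bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .extraction import TraceSet
from .io import GlomerulusMask, StimulusProtocol

__all__ = [
    "Stimulus",
    "SimConfig",
    "TuningMatrix",
    "stream",
    "pure_panel",
    "mixture_panel",
    "glomerulus_names",
    "mix_rule",
    "gen_tuning",
    "gen_traces",
    "grid_mask",
    "render_movie",
    "gen_volumes",
    "default_volume_shifts",
    "gen_trap_counts",
    "default_trap_conditions",
]

SPECIES = ("melanogaster", "suzukii")

# The 32 identifiable glomeruli, grouped by imaging depth: a superficial
# plane under the head capsule, and two deeper planes ~20 um apart.
_PLANE_1 = ("DA1", "DA2", "DA3", "DA4l", "DA4m", "DL4", "D")
_PLANE_2 = ("DL1", "DL3", "DL5", "DC1", "DC2", "DM2", "DM3", "DM5", "DM6",
            "VA1v", "VA1d", "VA6", "VM5v")
_PLANE_3 = ("DM1", "DM4", "VM2", "VM5d", "VM7v", "VM7d", "VA2", "VA5",
            "VA7", "VC1", "VC2", "VC3")
GLOMERULI_32 = _PLANE_1 + _PLANE_2 + _PLANE_3
PLANE_OF = {g: i + 1 for i, plane in enumerate((_PLANE_1, _PLANE_2, _PLANE_3))
            for g in plane}

PURE_ODOURS = (
    "ethyl acetate", "isoamyl acetate",            # ripening fruit
    "hexanal", "(Z)-3-hexenyl acetate",            # leaf
    "2-heptanone", "1-hexanol",                    # fermenting fruit
    "acetic acid", "geosmin",                      # microbial
)


def glomerulus_names(n: int) -> tuple[str, ...]:
    """First ``n`` channel names: the 32 identified glomeruli, then
    unidentified extras (the coding space has one more dimension than
    the morphologically identified set)."""
    extras = tuple(f"unidentified-{i + 1}" for i in range(max(0, n - 32)))
    return (GLOMERULI_32 + extras)[:n]


@dataclass(frozen=True)
class Stimulus:
    """A stimulus: a pure odorant or a two-component mixture."""

    name: str
    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 2:
            raise ValueError("stimuli are pure or two-component mixtures")

    @property
    def is_mixture(self) -> bool:
        return len(self.components) > 1


def pure_panel() -> tuple[Stimulus, ...]:
    """Eight single-odorant stimuli spanning ripening-fruit, leaf,
    fermenting-fruit and microbial volatiles."""
    return tuple(Stimulus(o, (o,)) for o in PURE_ODOURS)


def mixture_panel() -> tuple[Stimulus, ...]:
    """Four fruit/microbial components plus their four binary mixtures."""
    comps = ("ethyl acetate", "isoamyl acetate", "acetic acid", "geosmin")
    pures = tuple(Stimulus(o, (o,)) for o in comps)
    mixes = tuple(
        Stimulus(f"{a} + {b}", (a, b))
        for a in ("ethyl acetate", "isoamyl acetate")
        for b in ("acetic acid", "geosmin")
    )
    return pures + mixes


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all generators.

    Defaults follow the imaging protocol the analysis was designed for:
    10 Hz acquisition, 3 s stimulus after 2 s of recorded baseline, 10 s
    inter-stimulus interval, 10 trials per stimulus, 33 glomerular
    channels, and an asymmetric fly-gain spread (larger in
    ``species[0]``) on top of a moderate additive species shift of the
    odour code.
    """

    n_flies_per_species: int = 12
    n_glomeruli: int = 33
    odour_panel: tuple[Stimulus, ...] = field(default_factory=pure_panel)
    n_trials: int = 10
    frame_rate: float = 10.0
    stim_onset_s: float = 2.0
    stim_dur_s: float = 3.0
    isi_s: float = 10.0
    tau_rise_s: float = 0.3
    tau_decay_s: float = 1.0
    tonic_fraction: float = 0.2
    species_shift: float = 0.08
    sigma_fly: tuple[float, float] = (0.45, 0.15)
    sigma_trial: float = 2.0
    inhibition_strength: float = 0.0
    baseline_f0: float = 200.0
    n_sides: int = 1
    side_effect: float = 0.0
    species: tuple[str, str] = SPECIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glomeruli < 2:
            raise ValueError("need at least 2 glomeruli")
        if not self.odour_panel:
            raise ValueError("odour panel is empty")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.n_flies_per_species < 1:
            raise ValueError("need at least one fly per species")
        for name in ("frame_rate", "stim_onset_s", "stim_dur_s", "isi_s",
                     "tau_rise_s", "tau_decay_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.tonic_fraction <= 1.0:
            raise ValueError("tonic_fraction must lie in [0, 1]")
        if self.species_shift < 0:
            raise ValueError("species_shift must be non-negative")
        if self.inhibition_strength < 0:
            raise ValueError("inhibition_strength must be non-negative")
        if self.baseline_f0 <= 0:
            raise ValueError("baseline fluorescence must be positive")
        if self.n_sides not in (1, 2):
            raise ValueError("n_sides must be 1 or 2")

    # -- derived timing ---------------------------------------------------

    @property
    def n_frames(self) -> int:
        """Trial length: baseline + stimulus + the rest of the ISI."""
        return int(round(self.frame_rate * (self.stim_dur_s + self.isi_s)))

    @property
    def protocol(self) -> StimulusProtocol:
        onset = int(round(self.frame_rate * self.stim_onset_s))
        offset = int(round(self.frame_rate * (self.stim_onset_s + self.stim_dur_s)))
        return StimulusProtocol(self.frame_rate, onset, offset, self.n_frames)

    @property
    def glomeruli(self) -> tuple[str, ...]:
        return glomerulus_names(self.n_glomeruli)

    @property
    def stimulus_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.odour_panel)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def stream(seed: int, label: str) -> np.random.Generator:
    """Named, independent random substream of one root seed.

    Streams are derived as ``SeedSequence(seed, spawn_key=(crc32(label),))``,
    so every generator is reproducible on its own and the root seed fully
    determines all outputs.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class TuningMatrix:
    """Latent peak dF/F amplitudes, [glomerulus x stimulus], one species."""

    values: np.ndarray
    species: str
    glomeruli: tuple[str, ...]
    stimuli: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.glomeruli), len(self.stimuli)):
            raise ValueError("tuning matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite tuning values")
        if (self.values < 0).any():
            raise ValueError("tuning values must be non-negative")


def mix_rule(
    col_a: np.ndarray, col_b: np.ndarray, inhibition_strength: float = 0.0
) -> np.ndarray:
    """Divisive-normalization mixture response from two component columns.

    out_g = (a_g + b_g) / (1 + k * mean(a + b)); k = 0 is exact linear
    summation, larger k increasingly suppresses strong summed inputs
    (lateral-inhibition-style gain control).
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("component columns differ in length")
    if inhibition_strength < 0:
        raise ValueError("inhibition_strength must be non-negative")
    s = a + b
    return s / (1.0 + inhibition_strength * s.mean())


def gen_tuning(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    direction: np.ndarray | None = None,
) -> tuple[TuningMatrix, TuningMatrix]:
    """Ground-truth tuning matrices for the two species.

    Species A's responses to pure odorants are gamma-distributed peak
    amplitudes; species B's are A plus ``species_shift`` times a fixed
    per-(glomerulus, component) standard-normal direction (resampled per
    seed), rectified at zero.  Mixture columns of each species are
    computed from that species' own component columns via ``mix_rule``.

    ``direction`` overrides the random shift direction (same shape as
    the component matrix) for controlled experiments.
    """
    rng = rng if rng is not None else stream(config.seed, "tuning")
    G = config.n_glomeruli
    components: list[str] = []
    for stim in config.odour_panel:
        for c in stim.components:
            if c not in components:
                components.append(c)

    comp_a = rng.gamma(shape=2.0, scale=0.25, size=(G, len(components)))
    if direction is None:
        direction = rng.standard_normal((G, len(components)))
    else:
        direction = np.asarray(direction, dtype=float)
        if direction.shape != comp_a.shape:
            raise ValueError(
                f"direction shape {direction.shape} != component matrix "
                f"shape {comp_a.shape}"
            )
    comp_b = np.maximum(comp_a + config.species_shift * direction, 0.0)

    def assemble(comp: np.ndarray) -> np.ndarray:
        cols = []
        for stim in config.odour_panel:
            idx = [components.index(c) for c in stim.components]
            if len(idx) == 1:
                cols.append(comp[:, idx[0]])
            else:
                cols.append(
                    mix_rule(comp[:, idx[0]], comp[:, idx[1]],
                             config.inhibition_strength)
                )
        return np.column_stack(cols)

    gl, st = config.glomeruli, config.stimulus_names
    return (
        TuningMatrix(assemble(comp_a), config.species[0], gl, st),
        TuningMatrix(assemble(comp_b), config.species[1], gl, st),
    )


def response_kernel(config: SimConfig) -> np.ndarray:
    """Normalised temporal response shape h(t) over one trial.

    Zero before onset; saturating exponential rise (tau_rise) during the
    stimulus; after offset, exponential decay (tau_decay) toward a tonic
    plateau of ``tonic_fraction`` times the offset value.  The family
    spans phasic (tonic_fraction 0) through fully tonic responses.
    """
    p = config.protocol
    t = np.arange(config.n_frames) / config.frame_rate
    t_on = p.stim_onset / config.frame_rate
    t_off = p.stim_offset / config.frame_rate
    h = np.zeros(config.n_frames)
    during = (t >= t_on) & (t < t_off)
    h[during] = 1.0 - np.exp(-(t[during] - t_on) / config.tau_rise_s)
    h_off = 1.0 - np.exp(-(t_off - t_on) / config.tau_rise_s)
    after = t >= t_off
    tf = config.tonic_fraction
    h[after] = h_off * (tf + (1.0 - tf) * np.exp(-(t[after] - t_off) / config.tau_decay_s))
    return h


def gen_traces(
    config: SimConfig,
    tuning: tuple[TuningMatrix, TuningMatrix] | None = None,
    rng: np.random.Generator | None = None,
) -> TraceSet:
    """Raw fluorescence traces for every (fly, side, glomerulus, stimulus, trial).

    F(t) = F0 * (1 + g_fly * s_side * tuning * h(t)) + eps(t), with one
    log-normal gain g_fly per fly (median 1, log-sd ``sigma_fly`` of the
    fly's species), a multiplicative side factor (1 + side_effect) on
    the second brain side, and i.i.d. Gaussian trial noise of sd
    ``sigma_trial`` in raw-fluorescence units.
    """
    rng = rng if rng is not None else stream(config.seed, "traces")
    if tuning is None:
        tuning = gen_tuning(config)
    tun_a, tun_b = tuning
    expected = (config.n_glomeruli, len(config.odour_panel))
    for t in (tun_a, tun_b):
        if t.values.shape != expected:
            raise ValueError(
                f"tuning shape {t.values.shape} does not match config {expected}"
            )

    h = response_kernel(config)
    n_fly, n_side = config.n_flies_per_species, config.n_sides
    G, S, T, F = (config.n_glomeruli, len(config.odour_panel),
                  config.n_trials, config.n_frames)
    side_names = ("L", "R")[:n_side]
    side_gain = np.array([1.0, 1.0 + config.side_effect])[:n_side]
    f0 = config.baseline_f0

    blocks = []
    keys = []
    for sp_idx, (sp, tun) in enumerate(zip(config.species, (tun_a, tun_b))):
        gains = np.exp(config.sigma_fly[sp_idx] * rng.standard_normal(n_fly))
        # (fly, side, glom, stim, trial, frame)
        signal = f0 * (
            1.0
            + gains[:, None, None, None, None, None]
            * side_gain[None, :, None, None, None, None]
            * tun.values[None, None, :, :, None, None]
            * h[None, None, None, None, None, :]
        )
        # broadcast to full trial dimension before adding noise
        signal = np.broadcast_to(signal, (n_fly, n_side, G, S, T, F)).copy()
        if config.sigma_trial > 0:
            signal += rng.normal(0.0, config.sigma_trial, size=signal.shape)
        blocks.append(signal.reshape(-1, F))

        flies = [f"{sp[:3]}-{i + 1:02d}" for i in range(n_fly)]
        planes = [PLANE_OF.get(g, 3) for g in config.glomeruli]
        idx = pd.MultiIndex.from_product(
            [flies, side_names, list(config.glomeruli),
             list(config.stimulus_names), list(range(config.n_trials))],
            names=["fly", "side", "glomerulus", "odour", "trial"],
        )
        kdf = idx.to_frame(index=False)
        kdf.insert(0, "species", sp)
        kdf["plane"] = kdf["glomerulus"].map(dict(zip(config.glomeruli, planes)))
        keys.append(kdf)

    values = np.concatenate(blocks, axis=0)
    keydf = pd.concat(keys, ignore_index=True)
    cols = ["species", "fly", "side", "plane", "glomerulus", "odour", "trial"]
    return TraceSet(values, keydf[cols], config.protocol)


# ---------------------------------------------------------------------------
# Movies


def grid_mask(
    n_regions: int,
    region_shape: tuple[int, int] = (3, 3),
    gap: int = 1,
    names: list[str] | None = None,
) -> GlomerulusMask:
    """Disjoint rectangular regions laid out on a grid (each >= 4 px)."""
    if region_shape[0] * region_shape[1] < 4:
        raise ValueError("regions must contain at least 4 pixels")
    ncol = int(np.ceil(np.sqrt(n_regions)))
    nrow = int(np.ceil(n_regions / ncol))
    rh, rw = region_shape
    H = nrow * (rh + gap) + gap
    W = ncol * (rw + gap) + gap
    labels = np.zeros((H, W), dtype=np.int32)
    if names is None:
        names = list(glomerulus_names(n_regions))
    for i in range(n_regions):
        r, c = divmod(i, ncol)
        y0 = gap + r * (rh + gap)
        x0 = gap + c * (rw + gap)
        labels[y0:y0 + rh, x0:x0 + rw] = i + 1
    return GlomerulusMask(labels, {i + 1: names[i] for i in range(n_regions)})


def render_movie(
    traces: np.ndarray,
    mask: GlomerulusMask,
    rng: np.random.Generator | None = None,
    pixel_sd: float = 1.0,
    background: float = 0.0,
) -> np.ndarray:
    """Paint region traces into an image stack, plus i.i.d. pixel noise.

    Every pixel of region g at frame t has expected value ``traces[g, t]``;
    background pixels are constant.  The rendered movie is the round-trip
    test surface for :func:`glomcode.extraction.extract_traces`.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be (n_regions, n_frames)")
    labels = mask.sorted_labels
    if traces.shape[0] != len(labels):
        raise ValueError(
            f"{traces.shape[0]} traces for {len(labels)} mask regions"
        )
    n_frames = traces.shape[1]
    stack = np.full((n_frames,) + mask.labels.shape, background, dtype=float)
    for row, label in enumerate(labels):
        region = mask.region_pixels(label)
        stack[:, region] = traces[row][:, None]
    if pixel_sd > 0:
        if rng is None:
            raise ValueError("rng required when pixel_sd > 0")
        stack += rng.normal(0.0, pixel_sd, size=stack.shape)
    return stack


# ---------------------------------------------------------------------------
# Volumes


def default_volume_shifts(delta_pct: float = 1.0) -> dict[str, float]:
    """Balanced designed relative-volume shifts, in percentage points:
    three glomeruli larger and three smaller in the second species."""
    return {
        "DL1": +delta_pct, "DL5": +delta_pct, "DM4": +delta_pct,
        "VA1d": -delta_pct, "VA1v": -delta_pct, "VA2": -delta_pct,
    }


def gen_volumes(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_flies: int = 10,
    glomeruli: tuple[str, ...] = GLOMERULI_32,
    mean_fractions: np.ndarray | None = None,
    shifts: dict[str, float] | None = None,
    noise_sd: float = 0.10,
    fly_sd: float = 0.10,
    total_al_um3: float = 60000.0,
    al_ratio: float = 1.5,
) -> pd.DataFrame:
    """Per-fly absolute glomerular volumes for both species.

    The second species' total antennal-lobe volume is ``al_ratio`` times
    the first's (default 1.5, a 50 % larger AL).  Mean volume fractions
    are shared between species except for ``shifts`` (glomerulus ->
    offset in percentage points, applied to the second species and
    compensated on the unshifted glomeruli so fractions sum to 1 before
    noise).  Per-fly totals and per-(fly, glomerulus) volumes carry
    multiplicative log-normal noise of log-sd ``fly_sd``/``noise_sd``.
    """
    rng = rng if rng is not None else stream(config.seed, "volumes")
    n = len(glomeruli)
    if mean_fractions is None:
        raw = np.exp(0.3 * rng.standard_normal(n))
        frac_a = raw / raw.sum()
    else:
        frac_a = np.asarray(mean_fractions, dtype=float)
        if frac_a.shape != (n,):
            raise ValueError("mean_fractions length mismatch")
        frac_a = frac_a / frac_a.sum()

    shifts = shifts or {}
    unknown = [g for g in shifts if g not in glomeruli]
    if unknown:
        raise ValueError(f"shifted glomeruli not in set: {unknown}")
    frac_b = frac_a.copy()
    shifted_idx = np.array([glomeruli.index(g) for g in shifts], dtype=int)
    if shifted_idx.size:
        frac_b[shifted_idx] += np.array([shifts[g] for g in shifts]) / 100.0
        if (frac_b < 0).any():
            raise ValueError("designed shifts drive a fraction negative")
        others = np.setdiff1d(np.arange(n), shifted_idx)
        remainder = 1.0 - frac_b[shifted_idx].sum()
        frac_b[others] *= remainder / frac_b[others].sum()

    rows = []
    for sp, frac, total in zip(
        config.species, (frac_a, frac_b), (total_al_um3, total_al_um3 * al_ratio)
    ):
        for i in range(n_flies):
            fly_total = total * np.exp(fly_sd * rng.standard_normal())
            noise = np.exp(noise_sd * rng.standard_normal(n))
            vols = fly_total * frac * noise
            for g, v in zip(glomeruli, vols):
                rows.append(
                    {"species": sp, "fly": f"{sp[:3]}-{i + 1:02d}", "side": "R",
                     "glomerulus": g, "volume_um3": v}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trap counts


def default_trap_conditions() -> pd.DataFrame:
    """Seven bait-1/bait-2 pairings: each reference odour against itself,
    against its acetic-acid mixture, or against acetic acid alone."""
    rows = [
        ("ethyl acetate", "ethyl acetate"),
        ("ethyl acetate", "ethyl acetate + acetic acid"),
        ("ethyl acetate", "acetic acid"),
        ("isoamyl acetate", "isoamyl acetate"),
        ("isoamyl acetate", "isoamyl acetate + acetic acid"),
        ("isoamyl acetate", "acetic acid"),
        ("acetic acid", "acetic acid"),
    ]
    df = pd.DataFrame(rows, columns=["bait1_odour", "bait2_odour"])
    df.insert(0, "condition", [f"C{i + 1}:{b1} vs {b2}"
                               for i, (b1, b2) in enumerate(rows)])
    return df


#: Relative attractiveness of each odour source (identical across species:
#: mixtures with acetic acid are markedly more attractive than their
#: components, matching the preference structure the assay is meant to test).
DEFAULT_ATTRACTIVENESS = {
    "ethyl acetate": 3.0,
    "isoamyl acetate": 2.0,
    "acetic acid": 3.0,
    "ethyl acetate + acetic acid": 6.0,
    "isoamyl acetate + acetic acid": 6.0,
    "oil": 1.0,
    "empty": 1.0,
    "platform": 4.0,
}


def gen_trap_counts(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    conditions: pd.DataFrame | None = None,
    attractiveness: dict[str, float] | None = None,
    n_replicates: int = 8,
    n_flies_range: tuple[int, int] = (20, 50),
) -> pd.DataFrame:
    """Multinomial four-choice trap counts, ``n_replicates`` per condition.

    Each replicate releases a uniform random number of flies in
    ``n_flies_range`` (inclusive), distributed multinomially over
    {bait1, bait2, oil, empty, platform} according to the normalised
    attractiveness weights of the condition's bait odours.
    """
    rng = rng if rng is not None else stream(config.seed, "traps")
    if conditions is None:
        conditions = default_trap_conditions()
    attract = dict(DEFAULT_ATTRACTIVENESS)
    if attractiveness:
        attract.update(attractiveness)

    lo, hi = n_flies_range
    rows = []
    for sp in config.species:
        for _, cond in conditions.iterrows():
            w = np.array([
                attract[cond["bait1_odour"]],
                attract[cond["bait2_odour"]],
                attract["oil"],
                attract["empty"],
                attract["platform"],
            ], dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("invalid preference weights")
            p = w / w.sum()
            for rep in range(n_replicates):
                n = int(rng.integers(lo, hi + 1))
                counts = rng.multinomial(n, p)
                rows.append({
                    "species": sp,
                    "condition": cond["condition"],
                    "bait1_odour": cond["bait1_odour"],
                    "bait2_odour": cond["bait2_odour"],
                    "replicate": rep + 1,
                    "bait1": int(counts[0]),
                    "bait2": int(counts[1]),
                    "oil": int(counts[2]),
                    "empty": int(counts[3]),
                    "platform": int(counts[4]),
                })
    return pd.DataFrame(rows)
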