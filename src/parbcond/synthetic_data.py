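"""Synthetic inputs with the statistical structure each analysis assumes.

Every generator emits its ground truth alongside the data, so each analysis
stage has a closed-loop recovery test (generate -> analyze -> compare) and
no external datasets are needed.  Generators are bit-reproducible from
(config, seed).

Three families:
  * condensation kymographs/image stacks emulating SxG-stained stretched DNA
    with a localized condensate, optional photobleaching, and Poisson noise;
  * RNAP transcription traces (50 Hz) with programmed elongation and
    short/long pauses;
  * deterministic chain conformations (straight / hairpin / globule) for
    geometry unit tests of the recruitment and bridging rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .polymer_core import ChainState
from .rnap_dwell import TranscriptionTrace

__all__ = [
    "KymoSynthConfig",
    "TraceSynthConfig",
    "gen_condensation_kymograph",
    "gen_transcription_traces",
    "gen_test_chain",
    "hairpin_contact_pair",
]


@dataclass(frozen=True)
class KymoSynthConfig:
    """Synthetic DNA-stretching movie: geometry, condensate programme, noise.

    The DNA is rendered as a transverse-Gaussian band of `dna_length_px`
    along x; a condensate carries `fraction[t]` of the (conserved) total
    intensity as a Gaussian spot of width sigma_psf_px that diffuses with the
    given per-frame step.  Photon noise is Poisson at `photons_total` expected
    photons per frame; an optional bleach at `bleach_frame` drops the total to
    `bleach_residual` and recovers exponentially with `exchange_time_s`.
    """

    n_frames: int = 120
    ny: int = 31
    nx: int = 90
    dna_length_px: int = 62        # ~8 um at 0.13 um/px
    dna_sigma_y_px: float = 2.0
    sigma_psf_px: float = 1.5
    fraction: tuple = (0.5,)       # condensate intensity fraction per frame
    position_step_px: float = 0.3  # condensate diffusion (per-frame SD)
    photons_total: float = 2e5
    background: float = 20.0       # photons/px offset
    frame_interval_s: float = 1.0
    bleach_frame: int | None = None
    bleach_residual: float = 0.2
    exchange_time_s: float = 60.0

    def fraction_at(self, t: int) -> float:
        f = self.fraction[min(t, len(self.fraction) - 1)]
        if not 0.0 <= f <= 1.0:
            raise ValueError("fraction trajectory must lie in [0, 1]")
        return f


def gen_condensation_kymograph(cfg: KymoSynthConfig, seed: int = 0):
    """Image stack (n_frames, ny, nx) plus ground truth dict.

    Total intensity per frame is conserved up to noise (DNA conservation):
    the condensate Gaussian carries fraction[t] of the photons and the
    remaining 1-fraction is spread uniformly along the DNA band.
    Ground truth: per-frame fraction, spot position (px, in DNA-band
    coordinates), bleach scale factor, and the DNA band limits.
    """
    rng = np.random.default_rng(seed)
    ny, nx, T = cfg.ny, cfg.nx, cfg.n_frames
    x0 = (nx - cfg.dna_length_px) // 2
    x1 = x0 + cfg.dna_length_px - 1
    yc = ny // 2
    ys = np.arange(ny)
    prof_y = np.exp(-0.5 * ((ys - yc) / cfg.dna_sigma_y_px) ** 2)
    prof_y /= prof_y.sum()

    pos = cfg.dna_length_px / 2.0
    positions, fractions, scales = [], [], []
    stack = np.empty((T, ny, nx))
    xs = np.arange(nx)
    for t in range(T):
        f = cfg.fraction_at(t)
        pos = float(np.clip(pos + rng.normal(0.0, cfg.position_step_px),
                            5, cfg.dna_length_px - 6))
        scale = 1.0
        if cfg.bleach_frame is not None and t >= cfg.bleach_frame:
            dt = (t - cfg.bleach_frame) * cfg.frame_interval_s
            scale = cfg.bleach_residual + (1.0 - cfg.bleach_residual) * (
                1.0 - np.exp(-dt / cfg.exchange_time_s))
        total = cfg.photons_total * scale
        # uniform DNA part
        img_x = np.zeros(nx)
        img_x[x0:x1 + 1] += (1.0 - f) * total / cfg.dna_length_px
        # condensate spot
        spot = np.exp(-0.5 * ((xs - (x0 + pos)) / cfg.sigma_psf_px) ** 2)
        img_x += f * total * spot / spot.sum()
        expect = prof_y[:, None] * img_x[None, :] + cfg.background
        stack[t] = rng.poisson(expect)
        positions.append(pos)
        fractions.append(f)
        scales.append(scale)
    truth = {
        "fraction": np.asarray(fractions),
        "position_px": np.asarray(positions),
        "scale": np.asarray(scales),
        "dna_ends": ((x0, yc), (x1, yc)),
        "exchange_time_s": cfg.exchange_time_s,
        "bleach_frame": cfg.bleach_frame,
    }
    return stack, truth


@dataclass(frozen=True)
class TraceSynthConfig:
    """Programmed RNAP kinetics for synthetic transcription trajectories.

    Elongation proceeds at `rate_nt_s` interrupted, per 5-nt window, by a
    short pause with probability derived from `short_pause_per_nt` and a long
    pause from `long_pause_per_nt`.  Short-pause durations are uniform on
    `short_pause_s`, long on `long_pause_s` (chosen so total window dwells
    land in the 1-5 s and >5 s regions respectively).  Traces are sampled at
    `sampling_hz` with additive Gaussian noise and truncated at `max_nt`
    (the ~5000-nt transcribable construct length).
    """

    n_traces: int = 10
    rate_nt_s: float = 9.2
    short_pause_per_nt: float = 0.02
    long_pause_per_nt: float = 0.01
    short_pause_s: tuple = (1.2, 4.0)
    long_pause_s: tuple = (6.0, 20.0)
    sampling_hz: float = 50.0
    noise_sd_nt: float = 1.0
    max_nt: float = 5000.0
    window_nt: float = 5.0
    # window elongation times ~ Gamma with this shape and mode window/rate;
    # large shape keeps the elongation peak well inside 0.1-1 s so the three
    # dwell-time regions stay separable (see docs/methods.md)
    gamma_shape: float = 20.0

    @property
    def p_short_window(self) -> float:
        """Exact probability a 5-nt window contains a short pause."""
        return 1.0 - (1.0 - self.short_pause_per_nt) ** self.window_nt

    @property
    def p_long_window(self) -> float:
        return 1.0 - (1.0 - self.long_pause_per_nt) ** self.window_nt


def gen_transcription_traces(cfg: TraceSynthConfig, seed: int = 0):
    """List of TranscriptionTrace plus ground truth dict.

    Elongation through each 5-nt window takes a Gamma-distributed time
    (single-nt stepping) whose MODE is window_nt / rate_nt_s, so the
    peak-based elongation rate k = N / t_bar recovered by the analysis equals
    rate_nt_s by construction.  Pauses are assigned per window (at most one,
    long taking precedence) so the programmed window-wise pause probabilities
    are exact: truth p_short = P(short pause in a window), p_long likewise.
    """
    rng = np.random.default_rng(seed)
    traces = []
    dt = 1.0 / cfg.sampling_hz
    n_windows = int(cfg.max_nt / cfg.window_nt)
    g_scale = cfg.window_nt / cfg.rate_nt_s / (cfg.gamma_shape - 1.0)
    for _ in range(cfg.n_traces):
        # continuous-time position track built window by window
        knot_t = [0.0]
        knot_x = [0.0]
        t = 0.0
        for w in range(n_windows):
            u = rng.random()
            pause = 0.0
            if u < cfg.p_long_window:
                pause = rng.uniform(*cfg.long_pause_s)
            elif u < cfg.p_long_window + cfg.p_short_window:
                pause = rng.uniform(*cfg.short_pause_s)
            t_elong = rng.gamma(cfg.gamma_shape, g_scale)
            if pause > 0.0:
                # pause at a uniform point inside the window
                frac = rng.random()
                x_p = w * cfg.window_nt + frac * cfg.window_nt
                t_p = t + frac * t_elong
                knot_t.append(t_p)
                knot_x.append(x_p)
                knot_t.append(t_p + pause)
                knot_x.append(x_p)
                t = t_p + pause + (1.0 - frac) * t_elong
            else:
                t += t_elong
            knot_t.append(t)
            knot_x.append((w + 1) * cfg.window_nt)
        times = np.arange(0.0, t, dt)
        pos = np.interp(times, knot_t, knot_x)
        pos = pos + rng.normal(0.0, cfg.noise_sd_nt, size=len(pos))
        traces.append(TranscriptionTrace(times, pos, cfg.sampling_hz))
    truth = {
        "rate_nt_s": cfg.rate_nt_s,
        "p_short": cfg.p_short_window,
        "p_long": cfg.p_long_window,
        "mean_dwell_elongation_s": cfg.window_nt / cfg.rate_nt_s,
    }
    return traces, truth


# ------------------------------------------------------------- test chains

def hairpin_contact_pair(n_beads: int) -> tuple[int, int]:
    """The designed trans contact (i, j) of gen_test_chain('hairpin'):
    i mid-way along the outgoing strand, j its opposite on the return."""
    m = (n_beads - 2) // 2
    i = m // 2
    return i, 2 * m + 1 - i


def gen_test_chain(n_beads: int, conformation: str, seed: int = 0,
                   bond: float = 0.965) -> ChainState:
    """Deterministic conformations for unit tests.

    straight: beads along +x; every 1D separation >= 3 is >= 2.9 sigma away,
      so all trans neighbour lists are empty.
    hairpin: two antiparallel strands 1.8 sigma apart joined by a two-bead
      turn; a mid-strand bead has exactly its opposite within 2 sigma.
    globule: snake path through a compact cubic lattice; dense contacts.
    """
    if n_beads < 3:
        raise ValueError("need at least 3 beads")
    if conformation == "straight":
        pos = np.zeros((n_beads, 3))
        pos[:, 0] = np.arange(n_beads) * bond
    elif conformation == "hairpin":
        gap = 1.8
        m = (n_beads - 2) // 2
        rest = n_beads - 2 - 2 * m  # 0 or 1 extra bead on the return strand
        pos = np.zeros((n_beads, 3))
        for i in range(m):                      # outgoing strand
            pos[i] = (i * bond, 0.0, 0.0)
        xt = (m - 1) * bond + 0.8
        pos[m] = (xt, 0.25 * gap, 0.0)          # turn
        pos[m + 1] = (xt, 0.75 * gap, 0.0)
        for k in range(m + rest):               # return strand
            pos[m + 2 + k] = ((m - 1 - k) * bond, gap, 0.0)
    elif conformation == "globule":
        side = int(np.ceil(n_beads ** (1.0 / 3.0)))
        pos = np.zeros((n_beads, 3))
        i = 0
        dir_x, dir_y = 1, 1
        for z in range(side):
            yr = range(side) if dir_y == 1 else range(side - 1, -1, -1)
            for y in yr:
                xr = range(side) if dir_x == 1 else range(side - 1, -1, -1)
                for x in xr:
                    if i < n_beads:
                        pos[i] = (x * bond, y * bond, z * bond)
                        i += 1
                dir_x = -dir_x
            dir_y = -dir_y
    else:
        raise ValueError("conformation must be straight | hairpin | globule")
    return ChainState(pos, np.zeros_like(pos), rng_seed=seed)
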