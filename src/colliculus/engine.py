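"""Vectorized trial engine.

Runs a batch of independent trials that share one SynapseSet (weights are
read-only unless learning is enabled, which requires a single-trial batch).
All per-trial state (area activities, SG activity, gaze, FP delay, frozen
stimulus noise, lesion mask) is carried in arrays with a leading batch axis,
so a 500-trial calibration run costs a handful of matrix products per step.

Trials that already produced their saccade can be dropped from the batch
(``stop_when_all_saccaded``) when only latencies are of interest.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from numba import njit

from .core_dynamics import sigmoid
from .lesion import Patient
from .network import net_inputs
from .oculomotor import MIN_LATENCY, sample_fp_delay
from .params import AREAS, DEFAULT, N, POSITIONS, SOURCES, ModelParams
from .plasticity import HebbianEngine
from .stimulation import StimulusSpec, gaussian_profile, sample_trial_noise, shifted_noise
from .topology import SynapseSet

__all__ = ["BatchResult", "simulate_trials"]

_WTA_ORDER = np.lexsort((POSITIONS, np.abs(POSITIONS)))
_WTA_POS = POSITIONS[_WTA_ORDER]

# fused-state layout: all five areas concatenated into one 905-vector so a
# single matrix product computes every lateral + inter-area contribution
_ORDER = AREAS
_SL = {a: slice(k * N, (k + 1) * N) for k, a in enumerate(_ORDER)}
_NTOT = N * len(_ORDER)


class LatencyWarning(UserWarning):
    """A saccade fired below the 75 ms physiological floor."""


@dataclass
class BatchResult:
    """Per-trial outcomes of one engine run (aligned with the input specs)."""

    t_s: np.ndarray  # saccade onset (ms), NaN if none
    theta: np.ndarray  # saccade target (deg), NaN if none
    detected: np.ndarray  # bool
    t_detect: np.ndarray  # ms, NaN if not detected
    mediated: np.ndarray  # 'saccade' | 'restitution' | ''
    g_final: np.ndarray  # gaze at trial end (deg)
    t_end: np.ndarray  # per-trial simulated horizon (ms)
    traces: dict | None = None

    @property
    def latencies(self) -> np.ndarray:
        """Saccade latencies of trials that produced a saccade (ms)."""
        return self.t_s[~np.isnan(self.t_s)]

    @property
    def has_saccade(self) -> np.ndarray:
        return ~np.isnan(self.t_s)


def _shift_noise(noise_rows: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Re-index per-trial noise so it rides on each trial's stimulus center."""
    idx = POSITIONS[None, :] - np.rint(centers)[:, None].astype(int) + 90
    valid = (idx >= 0) & (idx < N)
    out = np.take_along_axis(noise_rows, np.clip(idx, 0, N - 1), axis=1)
    out[~valid] = 0.0
    return out


@njit(fastmath=True, cache=False)
def _gemv_core(y, blocks, src_off, tgt_off, n_inter, c32, ext, mask32, u):
    """Net-input mat-vec over the 17 connection blocks (single precision).

    ``blocks`` stacks the 12 transposed inter-area V-blocks followed by the
    5 lateral kernels; inter-area contributions are scaled by the
    per-neuron normalization factors ``c32`` before laterals are added,
    then the external input is applied and silenced V1 inputs clamped.
    """
    n = y.shape[0]
    for i in range(n):
        u[i] = 0.0
    for k in range(n_inter):
        so = src_off[k]
        to = tgt_off[k]
        u[to:to + 181] += np.dot(y[so:so + 181], blocks[k])
    for i in range(n):
        u[i] *= c32[i]
    for k in range(n_inter, blocks.shape[0]):
        so = src_off[k]
        to = tgt_off[k]
        u[to:to + 181] += np.dot(y[so:so + 181], blocks[k])
    for i in range(n):
        u[i] += ext[i]
    for i in range(181, 362):  # V1 slice: lesion clamp on net input
        u[i] *= mask32[i - 181]


class FusedContext:
    """Reusable factorized connectivity for sequential single-trial runs.

    Inter-area weights are stored as W^{H,Q}_{ij} = C_i^H * V^{H,Q}_{ij}:
    the multiplicative normalization of the learning rule then costs one
    vector update per step instead of a rescale of every incoming matrix.
    A training session builds the context once and carries it across its
    300 trials; ``writeback`` recomposes the current weights into the
    SynapseSet (done automatically at the end of a standalone trial).

    Attributes
    ----------
    v : (905, 905) float64
        Master V-matrix, block [source, target] = V^{H,Q} transposed
        (diagonal blocks zero). Double precision; only learning touches it.
    c : (905,) float64
        Per-postsynaptic-neuron normalization factors (1 at start; the
        retina is never normalized and keeps c = 1).
    blocks : (17, 181, 181) float32
        Single-precision kernel stack for the integration step: the 12
        transposed V-blocks followed by the 5 lateral kernels. Entries
        below 1e-30 (far Gaussian tails) are flushed to zero -- denormal
        arithmetic is orders of magnitude slower and the dropped
        contributions are negligible.
    views : dict[(target, source)] -> float32 view into ``blocks``
    src_off, tgt_off : int64 arrays
        State-vector offsets of each block's source/target area.
    c32, w_sg32 : float32 mirrors of ``c`` and the SC->SG weights.
    """

    def __init__(self, synapses: SynapseSet):
        self.synapses = synapses
        self.v = np.zeros((_NTOT, _NTOT))
        for (h, q), w in synapses.inter.items():
            self.v[_SL[q], _SL[h]] = w.T
        self.c = np.ones(_NTOT)
        conns = list(synapses.inter)
        n_blocks = len(conns) + len(_ORDER)
        self.n_inter = len(conns)
        self.blocks = np.empty((n_blocks, N, N), dtype=np.float32)
        self.src_off = np.empty(n_blocks, dtype=np.int64)
        self.tgt_off = np.empty(n_blocks, dtype=np.int64)
        self.views = {}
        tiny = 1e-30
        for k, (h, q) in enumerate(conns):
            w = synapses.inter[(h, q)].T
            self.blocks[k] = np.where(np.abs(w) < tiny, 0.0, w)
            self.src_off[k] = _SL[q].start
            self.tgt_off[k] = _SL[h].start
            self.views[(h, q)] = self.blocks[k]
        for k, a in enumerate(_ORDER):
            w = synapses.lateral[a]
            self.blocks[len(conns) + k] = np.where(np.abs(w) < tiny, 0.0, w)
            self.src_off[len(conns) + k] = _SL[a].start
            self.tgt_off[len(conns) + k] = _SL[a].start
        self.c32 = self.c.astype(np.float32)
        self.w_sg32 = synapses.w_sg.astype(np.float32)

    def writeback(self) -> None:
        """Recompose W = C * V into the SynapseSet's inter-area matrices."""
        for (h, q) in self.synapses.inter:
            self.synapses.inter[(h, q)][:] = (
                self.v[_SL[q], _SL[h]] * self.c[_SL[h]]
            ).T


def _active_range(y: np.ndarray, th: float):
    """(lo, hi) spanning all suprathreshold entries, or None."""
    idx = np.flatnonzero(y > th)
    if idx.size == 0:
        return None
    return int(idx[0]), int(idx[-1]) + 1


def _fused_learning_step(
    ctx: FusedContext,
    ranges: dict,
    y32: np.ndarray,
    y_sg: float,
    w_sg: np.ndarray,
    hebb: HebbianEngine,
) -> None:
    """One Hebbian increment + normalization cycle in W = C * V form.

    Mathematically identical to ``HebbianEngine.step`` (the reference
    implementation the test suite compares against): in W-space the
    increment is gamma0 (Wmax - W) [post]+ [pre]+, and the per-neuron
    normalization rescales each neuron's incoming sum back to its basal
    value; here the increment is applied to V (divided by C) and the
    rescale folds into C. Active neurons are addressed by the contiguous
    range spanning each area's suprathreshold set (precomputed once per
    step in ``ranges``) -- the rectified factors are exactly zero outside
    it, so interior sub-threshold dips contribute exactly nothing and
    untouched rows keep their factor at exactly 1.
    """
    p = hebb.params
    v, c, c32, views = ctx.v, ctx.c, ctx.c32, ctx.views
    for h in SOURCES:
        rng_h = ranges[h]
        if rng_h is None:
            continue
        lo_h, hi_h, yh = rng_h
        post = np.maximum(yh - p.threshold(h), 0.0)
        ch = c[_SL[h]][lo_h:hi_h]
        row_add = np.zeros(hi_h - lo_h)
        touched = False
        for q in SOURCES[h]:
            rng_q = ranges[q]
            if rng_q is None:
                continue
            lo_q, hi_q, yq = rng_q
            pre = np.maximum(yq - p.threshold(q), 0.0)
            vblk = v[_SL[q], _SL[h]]
            sub_v = vblk[lo_q:hi_q, lo_h:hi_h]
            w_sub = sub_v * ch
            delta_w = p.gamma0 * (hebb.wmax[(h, q)] - w_sub) * np.outer(pre, post)
            delta_v = delta_w / ch
            sub_v += delta_v
            views[(h, q)][lo_q:hi_q, lo_h:hi_h] += delta_v.astype(np.float32)
            row_add += delta_w.sum(axis=0)
            touched = True
        if not touched:
            continue
        base = hebb.basal_sums[h][lo_h:hi_h]
        factor = base / (base + row_add)
        c[_SL[h]][lo_h:hi_h] *= factor
        c32[_SL[h]][lo_h:hi_h] = c[_SL[h]][lo_h:hi_h]
    if y_sg > 0.0:
        rng_sc = ranges["SC"]
        if rng_sc is not None:
            lo, hi, ysc = rng_sc
            w_sg[lo:hi] += (
                p.gamma0
                * (hebb.wmax_sg - w_sg[lo:hi])
                * y_sg
                * np.maximum(ysc - p.y_th, 0.0)
            )
            ctx.w_sg32[lo:hi] = w_sg[lo:hi]


def _learning_ranges(y32: np.ndarray, params) -> dict:
    """Per-area contiguous suprathreshold ranges (lo, hi, float64 slice)."""
    ranges = {}
    for a in _ORDER:
        th = params.threshold(a)
        ya = y32[_SL[a]]
        r = _active_range(ya, th)
        ranges[a] = None if r is None else (r[0], r[1], ya[r[0]:r[1]].astype(np.float64))
    return ranges


def _simulate_single_fused(
    synapses: SynapseSet,
    spec: StimulusSpec,
    *,
    rng: np.random.Generator,
    lesion: Patient | None,
    eye_condition: str,
    fp_enabled: bool,
    learning: HebbianEngine | None,
    interrupt_on_detection: bool,
    horizon: float,
    params: ModelParams,
    ctx: FusedContext | None = None,
) -> BatchResult:
    """Single-trial runner on the fused 905-state (used for training trials).

    Same semantics as the batch path, about an order of magnitude faster
    per step for B = 1, which is what a 300-trial training session needs.
    The network step runs in single precision (the trajectories of the two
    paths agree to ~1e-5); all weight arithmetic is double precision.
    A caller that runs many sequential trials on the same SynapseSet (the
    training-session driver) passes a persistent ``ctx`` and calls
    ``ctx.writeback()`` when it needs the SynapseSet updated.
    """
    dt = params.dt
    oc = params.oculomotor
    st = params.stimulus
    dur = spec.duration
    fixed = eye_condition == "fixed"
    n_steps = int(round(horizon / dt))

    tn = sample_trial_noise(spec, rng, st)
    fp_delay = float(sample_fp_delay(rng, oc)) if fp_enabled else np.inf
    mask32 = (
        lesion.v1_mask().astype(np.float32)
        if lesion is not None
        else np.ones(N, dtype=np.float32)
    )

    def ext_vec(g: float) -> np.ndarray:
        ext = np.zeros(_NTOT, dtype=np.float32)
        if spec.has_visual:
            cc = spec.p - g
            er = gaussian_profile(st.v0, st.sigma_v, cc)
            er += shifted_noise(tn.visual, cc)
            ext[_SL["R"]] = np.maximum(er, 0.0)
        if spec.has_auditory:
            cc = spec.pa - g
            ea = gaussian_profile(st.a0, st.sigma_a, cc)
            ea += shifted_noise(tn.auditory, cc)
            ext[_SL["A"]] = np.maximum(ea, 0.0)
        return ext

    standalone = ctx is None
    if standalone:
        ctx = FusedContext(synapses)
    blocks, src_off, tgt_off = ctx.blocks, ctx.src_off, ctx.tgt_off
    n_inter, c32, w_sg32 = ctx.n_inter, ctx.c32, ctx.w_sg32
    w_sg = synapses.w_sg  # double-precision master, mutated by learning
    y = np.zeros(_NTOT, dtype=np.float32)
    y_sg = 0.0
    g = 0.0
    ext = ext_vec(g)
    sl_sc = _SL["SC"]

    t_s = np.nan
    theta = np.nan
    detected = False
    t_detect = np.nan
    mediated = ""
    t_end = float(horizon)
    interrupt_at = np.inf
    k32 = np.float32(dt / params.neuron.tau)
    k_sg = dt / params.sg_neuron.tau
    phi32 = np.float32(params.neuron.phi)
    y_th_det = params.y_th_detect
    t_off = params.learning.t_off
    u = np.empty(_NTOT, dtype=np.float32)
    one32 = np.float32(1.0)
    neg_xi32 = np.float32(-params.neuron.xi)
    tiny32 = np.float32(1e-30)
    sl_v1, sl_e = _SL["V1"], _SL["E"]
    lp = params.learning

    for i in range(1, n_steps + 1):
        t_prev = (i - 1) * dt
        t = i * dt
        _gemv_core(y, blocks, src_off, tgt_off, n_inter, c32, ext, mask32, u)
        u_sg = float(y[sl_sc] @ w_sg32)  # pre-step SC activities
        # sigmoid + forward Euler, in place, single precision
        u -= phi32
        u *= neg_xi32
        np.exp(u, out=u)
        u += one32
        np.reciprocal(u, out=u)  # u now holds F(u)
        u -= y
        u *= k32
        y += u
        np.clip(y, 0.0, 1.0, out=y)
        y[y < tiny32] = 0.0  # keep decaying activities out of denormal range
        y_v1 = y[sl_v1]
        y_v1 *= mask32
        v1max = float(y_v1.max())
        emax = float(y[sl_e].max())
        if not fixed:
            if fp_enabled and 0.0 <= t_prev - fp_delay <= dur:
                u_sg += oc.i0_fp
            f_sg = 1.0 / (1.0 + np.exp(-(u_sg - params.neuron.phi) * params.neuron.xi))
            y_sg = min(max(y_sg + k_sg * (f_sg - y_sg), 0.0), 1.0)
            if np.isnan(t_s) and y_sg >= oc.y_th_sg:
                if t < MIN_LATENCY:
                    warnings.warn(
                        f"saccade latency {t:.1f} ms below the {MIN_LATENCY:.0f} ms floor",
                        LatencyWarning,
                        stacklevel=2,
                    )
                t_s = t
                ysc = y[sl_sc]
                theta = float(_WTA_POS[np.argmax(ysc[_WTA_ORDER])])
            if not np.isnan(t_s) and g != theta:
                g_new = g + np.sign(theta - g) * oc.v_g * dt
                if (theta - g_new) * (theta - g) <= 0:
                    g_new = theta
                g = g_new
                ext = ext_vec(g)

        if not detected and t <= dur + 1e-9:
            if v1max > y_th_det and emax > y_th_det:
                detected = True
                t_detect = t
                mediated = "saccade" if (not np.isnan(t_s) and t_s < t) else "restitution"
                if interrupt_on_detection:
                    interrupt_at = min(max(t_detect, t_off) + 10.0, dur)

        if learning is not None and t >= t_off - 1e-9:
            ranges = _learning_ranges(y, lp)
            _fused_learning_step(ctx, ranges, y, y_sg, w_sg, learning)

        if t >= interrupt_at - 1e-9:
            t_end = t
            break

    if standalone and learning is not None:
        ctx.writeback()
    return BatchResult(
        t_s=np.array([t_s]),
        theta=np.array([theta]),
        detected=np.array([detected]),
        t_detect=np.array([t_detect]),
        mediated=np.array([mediated], dtype=object),
        g_final=np.array([float(g)]),
        t_end=np.array([t_end]),
        traces=None,
    )


def simulate_trials(
    synapses: SynapseSet,
    specs: Sequence[StimulusSpec],
    *,
    rng: np.random.Generator,
    lesion: Patient | Sequence[Patient | None] | None = None,
    eye_condition: str = "moving",
    fp_enabled: bool = False,
    learning: HebbianEngine | None = None,
    interrupt_on_detection: bool = False,
    stop_when_all_saccaded: bool = False,
    horizon: float | None = None,
    record_every: float | None = None,
    record_full: bool = False,
    params: ModelParams = DEFAULT,
    _fused: bool = True,
    _ctx: "FusedContext | None" = None,
) -> BatchResult:
    """Integrate a batch of trials from t = 0 to the trial horizon.

    Every trial starts from quiescence with the gaze at 0 deg. ``lesion``
    may be a single patient (applied to every trial), one entry per trial,
    or None (intact). Learning and the detection-interruption rule operate
    only on single-trial batches (training trials are sequential by nature).
    """
    if eye_condition not in ("moving", "fixed"):
        raise ValueError("eye_condition must be 'moving' or 'fixed'")
    B = len(specs)
    if B == 0:
        raise ValueError("empty trial batch")
    dur = specs[0].duration
    if any(s.duration != dur or s.onset != 0.0 for s in specs):
        raise ValueError("all trials in a batch must share duration and onset 0")
    if (learning is not None or interrupt_on_detection) and B != 1:
        raise ValueError("learning / interruption require a single-trial batch")
    if record_every is not None and stop_when_all_saccaded:
        raise ValueError("trace recording is incompatible with batch compaction")

    if (
        learning is not None
        and _fused
        and record_every is None
        and params.stimulus.noise_mode == "frozen"
    ):
        pat = lesion[0] if isinstance(lesion, (list, tuple)) else lesion
        return _simulate_single_fused(
            synapses,
            specs[0],
            rng=rng,
            lesion=pat,
            eye_condition=eye_condition,
            fp_enabled=fp_enabled,
            learning=learning,
            interrupt_on_detection=interrupt_on_detection,
            horizon=specs[0].duration if horizon is None else horizon,
            params=params,
            ctx=_ctx,
        )

    dt = params.dt
    oc = params.oculomotor
    st = params.stimulus
    y_th_det = params.y_th_detect
    fixed = eye_condition == "fixed"
    horizon = dur if horizon is None else horizon
    n_steps = int(round(horizon / dt))

    # --- per-trial inputs -------------------------------------------------
    pv = np.array([s.p for s in specs], dtype=float)
    pa = np.array([s.pa for s in specs], dtype=float)
    has_v = np.array([s.has_visual for s in specs])
    has_a = np.array([s.has_auditory for s in specs])
    noise_v = np.empty((B, N))
    noise_a = np.empty((B, N))
    for b, s in enumerate(specs):
        tn = sample_trial_noise(s, rng, st)
        noise_v[b] = tn.visual
        noise_a[b] = tn.auditory
    delta = (
        sample_fp_delay(rng, oc, B) if fp_enabled else np.full(B, np.inf)
    )
    if lesion is None:
        mask = None
    elif isinstance(lesion, Patient):
        mask = np.broadcast_to(lesion.v1_mask(), (B, N)).copy()
    else:
        if len(lesion) != B:
            raise ValueError("one lesion entry per trial required")
        mask = np.stack(
            [p.v1_mask() if p is not None else np.ones(N) for p in lesion]
        )

    def ext_rows(rows: np.ndarray, g_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cv = pv[rows] - g_rows
        er = gaussian_profile(st.v0, st.sigma_v, cv)
        er += _shift_noise(noise_v[rows], cv)
        er *= has_v[rows, None]
        np.maximum(er, 0.0, out=er)
        ca = pa[rows] - g_rows
        ea = gaussian_profile(st.a0, st.sigma_a, ca)
        ea += _shift_noise(noise_a[rows], ca)
        ea *= has_a[rows, None]
        np.maximum(ea, 0.0, out=ea)
        return er, ea

    # --- state ------------------------------------------------------------
    Y = {a: np.zeros((B, N)) for a in AREAS}
    y_sg = np.zeros(B)
    g = np.zeros(B)
    all_rows = np.arange(B)
    ext_r, ext_a = ext_rows(all_rows, g)

    # results (full batch size; live arrays may be compacted)
    res_ts = np.full(B, np.nan)
    res_theta = np.full(B, np.nan)
    res_det = np.zeros(B, dtype=bool)
    res_tdet = np.full(B, np.nan)
    res_med = np.full(B, "", dtype=object)
    res_g = np.zeros(B)
    res_tend = np.full(B, float(horizon))

    orig = all_rows.copy()  # live-row -> original index
    sacc = np.zeros(B, dtype=bool)
    theta = np.full(B, np.nan)

    traces: dict | None = None
    if record_every is not None:
        traces = {
            "t": [],
            "gaze": [],
            "y_sg": [],
            "max": {a: [] for a in AREAS},
        }
        if record_full:
            traces["y"] = {a: [] for a in AREAS}
        rec_stride = max(1, int(round(record_every / dt)))

        def _record(t: float) -> None:
            traces["t"].append(t)
            traces["gaze"].append(g.copy())
            traces["y_sg"].append(y_sg.copy())
            for a in AREAS:
                traces["max"][a].append(Y[a].max(axis=1))
                if record_full:
                    traces["y"][a].append(Y[a].copy())

        _record(0.0)

    k_neuron = dt / params.neuron.tau
    k_sg = dt / params.sg_neuron.tau
    interrupt_at = np.inf

    for i in range(1, n_steps + 1):
        t_prev = (i - 1) * dt
        t = i * dt

        if st.noise_mode == "per_step":
            nb = noise_v.shape[0]
            noise_v = rng.normal(0.0, st.noise_frac * st.v0, (nb, N))
            noise_a = rng.normal(0.0, st.noise_frac * st.a0, (nb, N))
            rows = np.arange(nb)
            ext_r, ext_a = ext_rows(rows, g)

        u = net_inputs(Y, synapses, ext_r, ext_a)
        if mask is not None:
            u["V1"] *= mask
        if not fixed:
            u_sg = Y["SC"] @ synapses.w_sg
            if fp_enabled:
                u_sg = u_sg + oc.i0_fp * (
                    (t_prev >= delta) & (t_prev <= delta + dur)
                )
        for a in AREAS:
            ya = Y[a]
            ya += k_neuron * (-ya + sigmoid(u[a], params.neuron))
            np.clip(ya, 0.0, 1.0, out=ya)
        if mask is not None:
            Y["V1"] *= mask
        if not fixed:
            y_sg += k_sg * (-y_sg + sigmoid(u_sg, params.sg_neuron))
            np.clip(y_sg, 0.0, 1.0, out=y_sg)

            new = np.flatnonzero(~sacc & (y_sg >= oc.y_th_sg))
            if new.size:
                if t < MIN_LATENCY:
                    warnings.warn(
                        f"saccade latency {t:.1f} ms below the {MIN_LATENCY:.0f} ms floor",
                        LatencyWarning,
                        stacklevel=2,
                    )
                sacc[new] = True
                ys = Y["SC"][new][:, _WTA_ORDER]
                theta[new] = _WTA_POS[np.argmax(ys, axis=1)]
                res_ts[orig[new]] = t
                res_theta[orig[new]] = theta[new]

            moving = np.flatnonzero(sacc & (g != theta))
            if moving.size:
                tg = theta[moving]
                g_old = g[moving]
                g_new = g_old + np.sign(tg - g_old) * oc.v_g * dt
                reached = (tg - g_new) * (tg - g_old) <= 0
                g_new[reached] = tg[reached]
                g[moving] = g_new
                er, ea = ext_rows(moving, g_new)
                ext_r[moving] = er
                ext_a[moving] = ea

        # conscious detection (both V1 and E above threshold, stimulus on)
        v1m = Y["V1"].max(axis=1)
        em = Y["E"].max(axis=1)
        if t <= dur + 1e-9:
            nd = np.flatnonzero(~res_det[orig] & (v1m > y_th_det) & (em > y_th_det))
            if nd.size:
                ondx = orig[nd]
                res_det[ondx] = True
                res_tdet[ondx] = t
                sm = sacc[nd] & (res_ts[ondx] < t)
                res_med[ondx[sm]] = "saccade"
                res_med[ondx[~sm]] = "restitution"
                if interrupt_on_detection:
                    # detection is acted upon within [T_off, D]: stop 10 ms
                    # after the first detected instant in that window, never
                    # beyond stimulus end
                    t_btn = max(res_tdet[ondx[0]], params.learning.t_off)
                    interrupt_at = min(t_btn + 10.0, dur)

        if learning is not None and t >= params.learning.t_off - 1e-9:
            learning.step(synapses, {a: Y[a][0] for a in AREAS}, float(y_sg[0]))

        if record_every is not None and i % rec_stride == 0:
            _record(t)

        if t >= interrupt_at - 1e-9:
            res_tend[orig] = t
            break

        if stop_when_all_saccaded:
            live = ~sacc
            n_live = int(live.sum())
            if n_live == 0:
                break
            if n_live < 0.75 * sacc.size and i % 50 == 0:
                keep = np.flatnonzero(live)
                orig = orig[keep]
                for a in AREAS:
                    Y[a] = Y[a][keep]
                y_sg = y_sg[keep]
                g = g[keep]
                theta = theta[keep]
                sacc = sacc[keep]
                pv, pa = pv[keep], pa[keep]
                has_v, has_a = has_v[keep], has_a[keep]
                noise_v, noise_a = noise_v[keep], noise_a[keep]
                delta = delta[keep]
                ext_r, ext_a = ext_r[keep], ext_a[keep]
                if mask is not None:
                    mask = mask[keep]

    res_g[orig] = g
    if traces is not None:
        traces["t"] = np.array(traces["t"])
        traces["gaze"] = np.stack(traces["gaze"]).T
        traces["y_sg"] = np.stack(traces["y_sg"]).T
        traces["max"] = {a: np.stack(v).T for a, v in traces["max"].items()}
        if record_full:
            traces["y"] = {a: np.stack(v) for a, v in traces["y"].items()}

    return BatchResult(
        t_s=res_ts,
        theta=res_theta,
        detected=res_det,
        t_detect=res_tdet,
        mediated=res_med,
        g_final=res_g,
        t_end=res_tend,
        traces=traces,
    )
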