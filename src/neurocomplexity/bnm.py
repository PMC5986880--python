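"""Stochastic brain-network simulation with conductance neural-mass nodes.

Each node is a mean-field model of a densely interconnected excitatory /
inhibitory population.  The state per node is ``(V, Z, W)``: mean excitatory
membrane potential, mean inhibitory membrane potential, and the fraction of
open potassium channels.  Sodium and calcium conductances follow sigmoid
voltage-dependent activation curves; the potassium conductance relaxes
exponentially toward its voltage-dependent equilibrium.  Population firing
rates are sigmoid functions ``Q_V(V)`` and ``Q_Z(Z)``.

Nodes are coupled through a structural connectome by long-range
excitatory-to-excitatory projections: the row-normalized weighted mean of
afferent firing rates enters node ``i``'s excitatory equation through the
AMPA- and NMDA-like synaptic terms, scaled by the global gain ``aee``.  The
within-node excitatory self-coupling keeps its default gain, so ``aee``
purely controls long-range interaction strength.  Oscillations arise from
the nonlinear instabilities of the node model itself (no external drive);
a small additive Wiener noise term on the excitatory equation keeps runs
stochastic.

Integration is Euler-Maruyama on a fine step, decimated to the requested
output rate; with zero noise the scheme is deterministic and seed
independent.  Default node constants live in ``data/nmm_constants.json``;
re-tuning means versioning that file, never editing numbers inline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from numba import njit

from .connectome import StructuralConnectome
from .signal import NodeTimeSeriesSet

__all__ = ["NMMParams", "SimulationError", "node_derivatives", "simulate", "default_constants"]


class SimulationError(RuntimeError):
    """Raised when the integration diverges (non-finite or unbounded state)."""


_CONST_KEYS = (
    "g_ca", "g_k", "g_l", "g_na", "v_ca", "v_k", "v_l", "v_na",
    "t_ca", "delta_ca", "t_k", "delta_k", "t_na", "delta_na",
    "v_t", "z_t", "delta_v", "delta_z", "q_v_max", "q_z_max",
    "a_ee", "a_ei", "a_ie", "a_ne", "a_ni", "b", "phi", "r_nmda", "i_ns",
)


def default_constants() -> dict[str, float]:
    """Node-model constants from the versioned parameter file."""
    text = resources.files("neurocomplexity.data").joinpath("nmm_constants.json").read_text()
    raw = json.loads(text)
    return {k: float(raw[k]) for k in _CONST_KEYS}


@dataclass(frozen=True)
class NMMParams:
    """Simulation parameters.

    Parameters
    ----------
    aee : float
        Long-range excitatory-to-excitatory gain (dimensionless; the swept
        quantity, meaningful over roughly [0, 0.55] with row-normalized
        connectomes).
    noise_volatility : float
        SD scale of the additive Wiener increment on the excitatory
        equation (per sqrt-unit-time); 0 gives a deterministic run.
    fs_out : float
        Output sampling rate in Hz.
    duration_samples : int
        Output samples retained after the burn-in.
    burn_in_s : float
        Initial stretch discarded, in seconds.
    substeps : int
        Integration steps per output sample.
    time_unit_s : float
        Physical duration of one model time unit.  The node equations are
        dimensionless with an intrinsic oscillation period of a few tens of
        time units; the default of 1 ms places that rhythm in the tens-of-Hz
        range at the default 200 Hz output rate.
    coupling_scale : float
        Fixed gain mapping ``aee`` onto the row-normalized connectome: the
        long-range term is ``coupling_scale * aee`` times the weighted mean
        afferent firing rate.  Calibrated once so that at the top of the
        swept range (``aee = 0.55``) the network remains itinerant —
        alternating synchronization and desynchronization — rather than
        locking into full synchrony.
    seed : int
        Seed for initial-condition perturbations and the noise path.
    constants : dict
        Node-model constants; defaults to the versioned parameter file.
    guard : float
        Bound on ``|V|`` and ``|Z|`` beyond which the run is declared
        divergent.
    """

    aee: float = 0.3
    noise_volatility: float = 0.001
    fs_out: float = 200.0
    duration_samples: int = 10_000
    burn_in_s: float = 2.0
    substeps: int = 20
    time_unit_s: float = 0.001
    coupling_scale: float = 0.72
    seed: int = 0
    constants: dict = field(default_factory=default_constants)
    guard: float = 20.0

    def __post_init__(self) -> None:
        if self.aee < 0:
            raise ValueError("aee must be non-negative")
        if self.noise_volatility < 0:
            raise ValueError("noise_volatility must be non-negative")
        if self.fs_out <= 0 or self.duration_samples < 1 or self.substeps < 1:
            raise ValueError("fs_out, duration_samples and substeps must be positive")

    @property
    def dt(self) -> float:
        """Integration step in model time units."""
        return 1.0 / (self.substeps * self.fs_out * self.time_unit_s)

    def with_(self, **kw) -> "NMMParams":
        return replace(self, **kw)


def _const_vector(c: dict[str, float]) -> np.ndarray:
    return np.array([c[k] for k in _CONST_KEYS], dtype=np.float64)


def node_derivatives(
    V: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
    aee: float,
    coupling_input: np.ndarray,
    constants: dict[str, float] | None = None,
):
    """Time derivatives of the node states (noise-free drift term).

    ``coupling_input[i]`` is the row-normalized weighted mean of afferent
    firing rates at node ``i``; it enters the excitatory equation scaled by
    ``aee`` alongside the local ``a_ee``-weighted self-excitation.  This is
    the reference NumPy implementation; the integration loop uses a compiled
    replica that is tested against it.
    """
    c = constants or default_constants()
    V = np.asarray(V, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(Z)) and np.all(np.isfinite(W))):
        raise SimulationError("non-finite state passed to node_derivatives")
    m_ca = 0.5 * (1.0 + np.tanh((V - c["t_ca"]) / c["delta_ca"]))
    m_na = 0.5 * (1.0 + np.tanh((V - c["t_na"]) / c["delta_na"]))
    m_k = 0.5 * (1.0 + np.tanh((V - c["t_k"]) / c["delta_k"]))
    q_v = 0.5 * c["q_v_max"] * (1.0 + np.tanh((V - c["v_t"]) / c["delta_v"]))
    q_z = 0.5 * c["q_z_max"] * (1.0 + np.tanh((Z - c["z_t"]) / c["delta_z"]))
    exc = c["a_ee"] * q_v + aee * np.asarray(coupling_input, dtype=np.float64)
    dV = (
        -(c["g_ca"] + c["r_nmda"] * exc) * m_ca * (V - c["v_ca"])
        - c["g_k"] * W * (V - c["v_k"])
        - c["g_l"] * (V - c["v_l"])
        - (c["g_na"] * m_na + exc) * (V - c["v_na"])
        - c["a_ie"] * Z * q_z
        + c["a_ne"] * c["i_ns"]
    )
    dZ = c["b"] * (c["a_ni"] * c["i_ns"] + c["a_ei"] * V * q_v)
    dW = c["phi"] * (m_k - W)
    return dV, dZ, dW


def firing_rate(V: np.ndarray, constants: dict[str, float] | None = None) -> np.ndarray:
    """Excitatory population firing rate ``Q_V``, the simulator's output."""
    c = constants or default_constants()
    return 0.5 * c["q_v_max"] * (1.0 + np.tanh((np.asarray(V) - c["v_t"]) / c["delta_v"]))


@njit(cache=True)
def _integrate(wnorm, aee, V, Z, W, c, dt, substeps, n_out, burn_steps, noise, guard):
    # c follows _CONST_KEYS ordering
    (g_ca, g_k, g_l, g_na, v_ca, v_k, v_l, v_na,
     t_ca, d_ca, t_k, d_k, t_na, d_na,
     v_t, z_t, d_v, d_z, qvm, qzm,
     a_ee, a_ei, a_ie, a_ne, a_ni, b, phi, r_nmda, i_ns) = (
        c[0], c[1], c[2], c[3], c[4], c[5], c[6], c[7],
        c[8], c[9], c[10], c[11], c[12], c[13],
        c[14], c[15], c[16], c[17], c[18], c[19],
        c[20], c[21], c[22], c[23], c[24], c[25], c[26], c[27], c[28],
    )
    n = V.size
    out = np.empty((n, n_out))
    q_v = np.empty(n)
    total_steps = burn_steps + n_out * substeps
    rec = 0
    for step in range(total_steps):
        for i in range(n):
            q_v[i] = 0.5 * qvm * (1.0 + np.tanh((V[i] - v_t) / d_v))
        for i in range(n):
            coup = 0.0
            for j in range(n):
                w = wnorm[i, j]
                if w != 0.0:
                    coup += w * q_v[j]
            vi = V[i]
            m_ca = 0.5 * (1.0 + np.tanh((vi - t_ca) / d_ca))
            m_na = 0.5 * (1.0 + np.tanh((vi - t_na) / d_na))
            m_k = 0.5 * (1.0 + np.tanh((vi - t_k) / d_k))
            q_zi = 0.5 * qzm * (1.0 + np.tanh((Z[i] - z_t) / d_z))
            exc = a_ee * q_v[i] + aee * coup
            dV = (
                -(g_ca + r_nmda * exc) * m_ca * (vi - v_ca)
                - g_k * W[i] * (vi - v_k)
                - g_l * (vi - v_l)
                - (g_na * m_na + exc) * (vi - v_na)
                - a_ie * Z[i] * q_zi
                + a_ne * i_ns
            )
            dZ = b * (a_ni * i_ns + a_ei * vi * q_v[i])
            dW = phi * (m_k - W[i])
            V[i] = vi + dt * dV + noise[step, i]
            Z[i] = Z[i] + dt * dZ
            W[i] = W[i] + dt * dW
        for i in range(n):
            if not (np.isfinite(V[i]) and np.isfinite(Z[i]) and np.isfinite(W[i])):
                return out, step
            if abs(V[i]) > guard or abs(Z[i]) > guard:
                return out, step
        if step >= burn_steps and (step - burn_steps) % substeps == substeps - 1:
            for i in range(n):
                out[i, rec] = 0.5 * qvm * (1.0 + np.tanh((V[i] - v_t) / d_v))
            rec += 1
    return out, -1


def initial_state(n: int, rng: np.random.Generator, constants: dict[str, float]):
    """Seeded per-node perturbation around a resting point of the node model.

    Nodes start slightly apart so the chaotic dynamics desynchronize them
    naturally instead of tracking a common trajectory.
    """
    V = -0.2 + rng.uniform(-0.1, 0.1, size=n)
    Z = 0.0 + rng.uniform(-0.05, 0.05, size=n)
    m_k = 0.5 * (1.0 + np.tanh((V - constants["t_k"]) / constants["delta_k"]))
    W = m_k + rng.uniform(-0.02, 0.02, size=n)
    return V, Z, np.clip(W, 0.0, 1.0)


def simulate(connectome: StructuralConnectome, params: NMMParams) -> NodeTimeSeriesSet:
    """Integrate the coupled network and return nodal firing-rate traces.

    Returns an ``n_nodes x duration_samples`` panel of the excitatory
    output variable (the sigmoid firing rate of ``V``) sampled at
    ``fs_out`` after the burn-in, carrying the connectome's node names and
    module labels.  Identical parameters and seed give identical output.

    Raises
    ------
    SimulationError
        If any state becomes non-finite or exceeds the guard bound; the
        message names the offending integration step and ``aee``.
    """
    n = connectome.n_nodes
    c = params.constants
    rng = np.random.default_rng(params.seed)
    V, Z, W = initial_state(n, rng, c)
    dt = params.dt
    burn_steps = int(round(params.burn_in_s * params.fs_out)) * params.substeps
    total_steps = burn_steps + params.duration_samples * params.substeps
    if params.noise_volatility > 0:
        noise = rng.standard_normal((total_steps, n)) * (
            params.noise_volatility * np.sqrt(dt)
        )
    else:
        noise = np.zeros((total_steps, n))
    out, bad_step = _integrate(
        np.ascontiguousarray(connectome.row_normalized()),
        float(params.aee * params.coupling_scale),
        V, Z, W,
        _const_vector(c),
        dt, params.substeps, params.duration_samples, burn_steps,
        noise, params.guard,
    )
    if bad_step >= 0:
        raise SimulationError(
            f"integration diverged at step {bad_step} (t={bad_step * dt:.4f} s) "
            f"with aee={params.aee}"
        )
    return NodeTimeSeriesSet(
        out, fs=params.fs_out, names=connectome.names, modules=connectome.modules
    )
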