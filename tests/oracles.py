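"""Independent reference implementations used as test oracles.

Everything here is written symbol-by-symbol from the model definition,
deliberately sharing no code with the package: a literal transcription of
the node equations, a fixed-step RK4 integrator, a brute-force search over
constant controls with its own trapezoid objective, and a chi-square tail
probability obtained by numerical quadrature of the density.
"""

import math

import numpy as np
from scipy.integrate import quad


def reference_rhs(x, topology, params, stimuli=()):
    """Literal transcription of the SQUAD node equations.

    ``stimuli`` is a list of (node_id, direction, delta, u) tuples.
    Loops over nodes and regulators explicitly; no vectorization, no reuse
    of package code.
    """
    ids = [n.id for n in topology.nodes]
    deriv = []
    for node in topology.nodes:
        if node.kind == "constant":
            deriv.append(0.0)
            continue
        j = ids.index(node.id)
        activators = [e.source for e in topology.edges
                      if e.target == node.id and e.sign == "activating"]
        inhibitors = [e.source for e in topology.edges
                      if e.target == node.id and e.sign == "inhibiting"]
        # combined input w
        if activators or inhibitors:
            if activators:
                sum_a = sum(params.activator_weights[(a, node.id)]
                            for a in activators)
                sum_ax = sum(params.activator_weights[(a, node.id)]
                             * x[ids.index(a)] for a in activators)
                act = ((1 + sum_a) / sum_a) * (sum_ax / (1 + sum_ax))
            if inhibitors:
                sum_b = sum(params.inhibitor_weights[(i, node.id)]
                            for i in inhibitors)
                sum_bx = sum(params.inhibitor_weights[(i, node.id)]
                             * x[ids.index(i)] for i in inhibitors)
                inh = ((1 + sum_b) / sum_b) * (sum_bx / (1 + sum_bx))
            if activators and inhibitors:
                w = act * (1 - inh)
            elif activators:
                w = act
            else:
                w = 1 - inh
            h = params.steepness[node.id]
            activation = ((-math.exp(0.5 * h) + math.exp(-h * (w - 0.5)))
                          / ((1 - math.exp(0.5 * h))
                             * (1 + math.exp(-h * (w - 0.5)))))
        else:
            activation = 0.0
        r = 0.0
        for (target, direction, delta, u) in stimuli:
            if target != node.id:
                continue
            if direction == "up":
                r += delta * u * (1 - x[j])
            else:
                r += -delta * u * x[j]
        deriv.append(activation - params.decay[node.id] * x[j] + r)
    return np.array(deriv)


def rk4_integrate(x0, t_end, topology, params, stimuli=(), dt=1e-4):
    """Classical fixed-step RK4 on the reference right-hand side."""
    x = np.array(x0, dtype=float)
    n_steps = int(round(t_end / dt))

    def f(state):
        return reference_rhs(state, topology, params, stimuli)

    for _ in range(n_steps):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


def rk4_trajectory(x0, times, topology, params, stimuli=(), dt=1e-4):
    """RK4 states at each requested time (times must start at 0)."""
    out = [np.array(x0, dtype=float)]
    for t_lo, t_hi in zip(times[:-1], times[1:]):
        out.append(rk4_integrate(out[-1], t_hi - t_lo, topology, params,
                                 stimuli, dt))
    return np.array(out)


def chi2_sf_quadrature(value, dof):
    """Upper-tail chi-square probability by integrating the density."""
    if value <= 0:
        return 1.0

    def pdf(t):
        return (t ** (dof / 2.0 - 1.0) * math.exp(-t / 2.0)
                / (2.0 ** (dof / 2.0) * math.gamma(dof / 2.0)))

    tail, _ = quad(pdf, value, np.inf, limit=200)
    return tail


def brute_force_constant_control(topology, params, channel, rho, theta,
                                 horizon, alpha, u_levels, x0, dt=1e-3,
                                 n_report=501):
    """Exhaustive search over constant controls for a single channel.

    The objective is evaluated with RK4 on the reference equations and a
    trapezoid rule on a fine reporting grid — fully independent of the
    package's solver and quadrature.
    """
    node_id, direction, delta = channel
    ids = [n.id for n in topology.nodes]
    times = np.linspace(0.0, horizon, n_report)
    best_u, best_obj = None, np.inf
    target_col = ids.index(theta[0])
    theta_value = theta[1]
    for u in u_levels:
        stimuli = [(node_id, direction, delta, u)]
        states = rk4_trajectory(x0, times, topology, params, stimuli, dt)
        tracking = np.trapezoid(
            rho * (states[:, target_col] - theta_value) ** 2, times)
        cost = alpha * u * horizon
        obj = tracking + cost
        if obj < best_obj:
            best_obj, best_u = obj, u
    return best_u, best_obj
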