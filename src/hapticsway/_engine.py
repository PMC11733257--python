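"""Numba kernel for the closed-loop stance simulation.

The loop is inherently sequential (delayed feedback), so it is compiled
rather than vectorised.  All model logic that depends on time-step ordering
lives here; parameter handling and validation live in :mod:`model_core`.

Discrete-time conventions (step k, fixed step ``dt``):

* noise state   n[k+1] = a*n[k] + (1-a)*k_noise*w[k],  a = exp(-dt/tau)
  (exact zero-order-hold discretisation of a first-order low-pass driven
  by the piecewise-constant input u[k] = k_noise*w[k], w[k] ~ N(0,1))
* noise slope   ndot[k] = (k_noise*w[k] - n[k]) / tau  (analytic derivative
  of the held-input filter, so position and velocity cues are consistent)
* plant         semi-implicit Euler:
                theta_dot[k+1] = theta_dot[k] + dt*(mgh*theta[k] - torque[k])/J
                theta[k+1]     = theta[k] + dt*theta_dot[k+1]
* delay         torque[k] = Kp*that[k-d] + Kd*vhat[k-d], zero pre-history
"""

import numpy as np
from numba import njit

# Body angle (rad) beyond which the run is declared divergent.  Far outside
# the small-angle regime; a stabilised loop never gets close.
DIVERGENCE_LIMIT = 0.5


@njit(cache=True)
def simulate_loop(
    n_steps,
    dt,
    mgh,
    J,
    Kp,
    Kd,
    delay_steps,
    w_touch,
    w_space,
    G,
    lag_steps,
    h,
    Te,
    deadzone,
    leak_rate,
    k_noise,
    a_noise,
    tau_noise,
    w,
    theta,
    theta_dot,
    x_robot,
    theta_touch,
    theta_space,
    conflict,
    torque,
    noise,
):
    """Run the closed loop for ``n_steps``; fill the output arrays in place.

    Returns the number of valid steps (== n_steps unless the loop diverged).
    """
    that_hist = np.zeros(n_steps)
    vhat_hist = np.zeros(n_steps)

    th = 0.0
    td = 0.0
    n_state = 0.0
    b_noise = (1.0 - a_noise) * k_noise
    z = 0.0  # leaky integral of the conflict correction (position-cue term)
    inv_h = 1.0 / h
    inv_tau = 1.0 / tau_noise
    inv_J = 1.0 / J
    conflict_on = np.isfinite(Te)

    for k in range(n_steps):
        n = n_state
        ndot = (k_noise * w[k] - n) * inv_tau

        x_body = h * th
        if lag_steps == 0:
            xb_d = x_body
            vb_d = h * td
        elif k >= lag_steps:
            xb_d = h * theta[k - lag_steps]
            vb_d = h * theta_dot[k - lag_steps]
        else:
            xb_d = 0.0
            vb_d = 0.0
        x_rob = G * xb_d

        # touch channel: horizontal hand-body distance mapped back to angle
        s = x_rob - x_body
        sdot = G * vb_d - h * td
        th_t = -s * inv_h + n
        v_t = -sdot * inv_h + ndot

        # space channel
        th_s = th + n
        v_s = td + ndot

        # conflict estimator on the velocity cues
        d = v_t - v_s
        c = 0.0
        if conflict_on:
            if d > Te:
                c = d - Te if deadzone else d
            elif d < -Te:
                c = d + Te if deadzone else d

        th_t_corr = th_t - z
        v_t_corr = v_t - c

        that = w_space * th_s + w_touch * th_t_corr
        vhat = w_space * v_s + w_touch * v_t_corr
        that_hist[k] = that
        vhat_hist[k] = vhat

        if k >= delay_steps:
            trq = Kp * that_hist[k - delay_steps] + Kd * vhat_hist[k - delay_steps]
        else:
            trq = 0.0

        theta[k] = th
        theta_dot[k] = td
        x_robot[k] = x_rob
        theta_touch[k] = th_t_corr
        theta_space[k] = th_s
        conflict[k] = c
        torque[k] = trq
        noise[k] = n

        # state updates
        z += dt * (c - leak_rate * z)
        n_state = a_noise * n_state + b_noise * w[k]
        td = td + dt * (mgh * th - trq) * inv_J
        th = th + dt * td

        if abs(th) > DIVERGENCE_LIMIT or not np.isfinite(th):
            return k + 1

    return n_steps
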