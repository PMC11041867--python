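"""Independent brute-force oracles used by the test suite."""

import numpy as np


def kappa_point_charge(mu_D_hat, mu_A_hat, r_vec, d_over_r=1e-3):
    """Orientation factor via a finite point-charge dipole pair.

    Each transition dipole is represented as charges ±q separated by d
    along its axis (q·d = μ, here μ = 1 in reduced units with 4πε₀ = 1).
    The Coulomb interaction energy of the two charge pairs, divided by
    μ_D μ_A / r³, converges to κ as d/r → 0.  Independent of the
    analytic dot-product formula it checks.
    """
    mu_D_hat = np.asarray(mu_D_hat, float)
    mu_A_hat = np.asarray(mu_A_hat, float)
    r_vec = np.asarray(r_vec, float)
    r = np.linalg.norm(r_vec)
    d = d_over_r * r
    q = 1.0 / d  # so that q * d = 1

    donor_charges = [(+q, +0.5 * d * mu_D_hat), (-q, -0.5 * d * mu_D_hat)]
    acceptor_charges = [
        (+q, r_vec + 0.5 * d * mu_A_hat),
        (-q, r_vec - 0.5 * d * mu_A_hat),
    ]
    energy = 0.0
    for qi, pi in donor_charges:
        for qj, pj in acceptor_charges:
            energy += qi * qj / np.linalg.norm(pi - pj)
    return energy * r**3  # κ = V / (μ_D μ_A / r³), μ = 1
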