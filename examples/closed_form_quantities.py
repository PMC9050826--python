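"""Evaluate the closed-form scalar quantities of the wave family.

For wave speed c and production rate r, the analysis pins down: the critical
inactive density i_c below which no nonnegative wave can settle, the
eigenvalues at a steady state (0, 0, K), the asymptotic decay rates of a wave
tail, and the algebraic limit map that sends an initial state (a0, 0, i0) to
its final inactive density.
"""

import branchwave as bw

params = bw.ModelParams(c=2.0, r=0.0)
K, a0, i0 = 2.0, 0.1, 0.5

print(f"parameters: c={params.c}, r={params.r}")
print(f"critical density i_c(c)        = {bw.critical_density(params.c):.6f}")

es = bw.fixed_point_eigensystem(params, K)
print(f"eigenvalues at (0,0,{K})       = 0, {es.lambda_plus:.6f}, {es.lambda_minus:.6f}")

mu, kind = bw.decay_rate(params, 0.2)
print(f"tail rate at i=0.2             = {mu:.6f} ({kind})")

print(f"limit map i_inf(a0={a0}, i0={i0}) = {bw.limit_map(a0, i0, params):.6f}")
print(f"alpha threshold alpha(i0={i0})  = {bw.alpha_threshold(i0, params):.6f}")
print(f"attractor bound a*(i0={i0})     = {bw.a_star(i0, params):.6f}")

# The limit map says: an orbit started at (0.1, 0, 0.5) settles at inactive
# density ~0.398; starts up to a* ~0.472 stay nonnegative and converge, and
# the start exactly at alpha(i0) drains the inactive density to i_c.
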