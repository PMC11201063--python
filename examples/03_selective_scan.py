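"""The selective state-space scan behind the Mamba skip module.

Runs the causal recurrence h_t = exp(dt*A) h_{t-1} + dt*B_t u_t,
y_t = C_t.h_t + D u_t on a toy sequence, verifies it against a plain
python loop, and demonstrates causality: perturbing one timestep never
changes earlier outputs.
"""
import numpy as np

from lightcf import nn
from lightcf.nn.scan import selective_scan

rng = np.random.default_rng(0)
L, c, n = 10, 2, 4
u = rng.normal(size=(1, L, c))
dt = rng.uniform(0.1, 0.8, (1, L, c))
A = -rng.uniform(0.5, 1.5, (c, n))
B = rng.normal(size=(1, L, n))
C = rng.normal(size=(1, L, n))
D = np.ones(c)

y = selective_scan(*map(nn.Tensor, (u, dt, A, B, C, D))).data

h = np.zeros((c, n))
ref = np.zeros_like(y)
for t in range(L):
    h = np.exp(dt[0, t][:, None] * A) * h + dt[0, t][:, None] * B[0, t] * u[0, t][:, None]
    ref[0, t] = h @ C[0, t] + D * u[0, t]
print("max |scan - naive loop| =", np.abs(y - ref).max())

u2 = u.copy()
u2[0, 6] += 5.0
y2 = selective_scan(*map(nn.Tensor, (u2, dt, A, B, C, D))).data
print("outputs before the perturbed step changed:",
      bool(np.any(y[0, :6] != y2[0, :6])))
print("outputs from the perturbed step on changed:",
      bool(np.any(y[0, 6:] != y2[0, 6:])))
# The first flag must be False (strict causality), the second True.
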