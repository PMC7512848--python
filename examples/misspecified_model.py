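"""What the estimator converges to when the model is wrong.

For a cell-probability vector pi outside the family, the minimum penalized
divergence estimate converges to the projection parameter theta_0 (the
best-approximating member), and sqrt(n) (theta_hat - theta_0) is still
asymptotically normal with the sandwich-style covariance computed here.
The centered divergence statistic has limiting variance rho2.
"""

import numpy as np

from penphi import (
    asymptotic_covariance,
    fit_mpe,
    get_model,
    misspec_summary,
    power_divergence,
)

model = get_model("example1")  # p(t) = (1/3 - t, 2/3 - t, 2t)
phi = power_divergence(1)      # Pearson generator
pi = np.array([0.25, 0.35, 0.40])  # not in the family

s = misspec_summary(pi, model, phi, 1.0, phi, 1.0)
cov = asymptotic_covariance(pi, model, s.theta0, phi, 1.0)
print(f"pi = {pi.tolist()} (outside the family)")
print(f"projection parameter theta_0  = {s.theta0[0]:.6f}")
print(f"limiting divergence           = {s.limit_divergence:.6f}")
print(f"avar of sqrt(n)(theta_hat - theta_0) = {cov[0, 0]:.6f}")
print(f"rho2 (variance of the centered statistic) = {s.rho2:.6f}")

# a large simulated sample lands near the projection, as the theory says
rng = np.random.default_rng(0)
n = 50_000
X = rng.multinomial(n, pi)
est = fit_mpe(X, model, phi, 1.0)
se = np.sqrt(cov[0, 0] / n)
print(f"\none sample of n={n}: theta_hat = {est.theta_hat[0]:.6f} "
      f"(theta_0 +/- 2 se = {s.theta0[0]:.6f} +/- {2 * se:.6f})")
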