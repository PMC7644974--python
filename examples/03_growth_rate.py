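"""Estimate the instantaneous specific growth rate from an OD720 series.

The culture grows under a 14 h half-sine photoperiod peaking at 600 umol
photons m^-2 s^-1.  We integrate the light-driven growth law, then recover
mu(t) = d ln(OD720)/dt from the series alone and locate its peak.
"""

import numpy as np

from isodiel import LightProfile, instantaneous_mu, simulate_od

profile = LightProfile(peak=600.0, dawn=5.0, photoperiod=14.0, cycle=24.0)
mu_peak = 1.43 * np.pi / (2 * profile.photoperiod)  # ln-growth 1.43 per photoperiod

series = simulate_od(profile, mu_peak=mu_peak, od0=0.1, dt=0.05, horizon=48.0)
est = instantaneous_mu(series, window=1)

second_cycle = (series.time_h >= 24.0) & (series.time_h < 48.0)
i = np.argmax(np.where(second_cycle, est.mu, -np.inf))
print(f"planted peak mu : {mu_peak:.4f} /h")
print(f"recovered peak  : {est.mu[i]:.4f} /h at t = {series.time_h[i]:.2f} h")
print(f"OD720 gain over day 2: x{series.od720[second_cycle][-1] / series.od720[second_cycle][0]:.2f}")
# The recovered peak (~0.16 /h) sits at mid-photoperiod (t = 36 h, i.e.
# dawn + 7 h of day 2), as expected for purely light-limited growth.
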