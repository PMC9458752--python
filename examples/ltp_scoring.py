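"""fEPSP slope measurement, theta-burst timing and LTP magnitude.

Measures the initial slope of a constructed field sweep, prints the
theta-burst induction timestamps, and scores a simulated LTP experiment.
"""

from ephyskit import fepsp, synth

sweep = synth.gen_fepsp_sweep(slope_mv_per_ms=-0.5, volley_amp_mv=0.2)
m = fepsp.measure_fepsp(sweep)
print(f"fiber volley: {m.fiber_volley_mv:.3f} mV   "
      f"fEPSP slope: {m.slope_mv_per_ms:.3f} mV/ms")

times = fepsp.theta_burst_times()
print(f"theta-burst protocol: {times.size} pulses, "
      f"first burst at {times[:4]} s, last pulse at {times[-1]:.2f} s")

tc = synth.gen_ltp_session(potentiation_factor=1.65, noise_cv=0.03, seed=9)
print(f"LTP magnitude (last 10 min, % of baseline): "
      f"{fepsp.ltp_magnitude(tc):.1f}%")
# 100% means no potentiation; a 1.65x slope step yields ~165%.
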