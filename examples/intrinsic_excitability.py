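"""Passive membrane properties, F-I curve and spike-frequency adaptation.

Simulates an adaptive integrate-and-fire neuron through the standard
current-step ladder (-100..+500 pA, 50-pA increments, 1 s) and an ideal-RC
voltage-clamp step, then recovers the intrinsic-excitability metrics.
"""

from ephyskit import intracellular as ic, synth

# passive properties from a -5 mV hyperpolarising step (ideal RC cell)
sweep = synth.gen_rc_step_sweep(r_mohm=200.0, cm_pf=65.0)
p = ic.passive_properties(sweep)
print(f"input resistance: {p.input_resistance_mohm:.1f} MOhm  "
      f"capacitance: {p.capacitance_pf:.1f} pF  "
      f"tau: {p.time_constant_ms:.1f} ms")

session = synth.gen_current_step_session(seed=3)
steps, counts = ic.fi_curve(session)
print("F-I curve (step pA -> spikes/s):")
print("  ", {int(s): int(c) for s, c in zip(steps, counts)})
print(f"closed-form rheobase: {session.params.rheobase_pa:.0f} pA")

step, times = ic.select_sfa_step(session)
print(f"SFA (ISI3/ISI5) at the {step:.0f}-pA step: "
      f"{ic.sfa_index(times):.3f}")
# SFA < 1 indicates lengthening inter-spike intervals, i.e. adaptation.
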