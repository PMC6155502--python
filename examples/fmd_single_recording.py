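"""Analyze a single flow-mediated dilation recording.

Builds a synthetic brachial-artery recording (baseline 0.30 cm, a true
8% dilation peaking 30 s after cuff release, realistic measurement
noise) and runs the single-trace FMD analysis.
"""

from vasoreact import FmdSimParams, analyze_trace, generate_fmd_trace

trace = generate_fmd_trace(FmdSimParams(
    baseline_diameter=0.30,     # cm
    fmd_percent=8.0,            # programmed true dilation
    time_to_peak=30.0,          # s after cuff release
    noise_sd_diameter=0.002,    # cm (~20 um edge-detection noise)
    noise_sd_velocity=1.0,      # cm/s Doppler noise
    seed=42,
))
result = analyze_trace(trace)

print(f"baseline diameter : {result.baseline_diameter:.4f} cm")
print(f"peak diameter     : {result.peak_diameter:.4f} cm")
print(f"time to peak      : {result.time_to_peak:.1f} s")
print(f"%FMD              : {result.fmd_percent:.2f} %")
print(f"cumulative SR     : {result.cumulative_sr:.0f}")
print(f"%FMD / SR         : {result.fmd_per_sr:.3e}")
print(f"flow AUC (0-120s) : {result.flow_auc:.0f} ml")
# %FMD is the percent diameter gain at peak; cumulative SR is the shear
# stimulus integrated from release to peak, used to normalize %FMD so that
# recordings with different hyperaemic stimuli become comparable.
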