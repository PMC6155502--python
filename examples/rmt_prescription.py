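"""Eight-week isocapnic-hyperpnoea training schedule.

Starting from a participant's spirometry (FVC 4.10 l, MVV 134 l/min):
tidal volume at 50% FVC, minute-ventilation target at 60% MVV, and a
~15% weekly workload increment alternating between volume and frequency.
"""

from vasoreact import initial_prescription, schedule

p = initial_prescription(fvc=4.10, mvv=134.0)
print(f"week 1: V_T = {p.tidal_volume:.2f} l, "
      f"f_b = {p.breath_frequency:.1f} breaths/min, "
      f"MV target = {p.target_minute_ventilation:.1f} l/min")

table = schedule(fvc=4.10, mvv=134.0, weeks=8)
print(table.round(2).to_string(index=False))
ratio = (table["minute_ventilation_l_min"].iloc[-1]
         / table["minute_ventilation_l_min"].iloc[0])
print(f"week-8 workload is {ratio:.2f}x week 1 (1.15^7 = {1.15**7:.2f})")
# The V_T * f_b product rises by exactly 15% per week no matter which
# parameter carries the increment, so the cumulative dose is 1.15^(w-1).
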