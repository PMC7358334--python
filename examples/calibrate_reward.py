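"""Convert between solenoid open times and dispensed reward volumes.

The reward solenoid is characterized by a linear calibration: volume in
milliliters against open time in seconds.  The box firmware works in whole
milliseconds, rounding down so a dispense never exceeds its target.
"""

from nosepoke import DEFAULT_CALIBRATION, CalibrationModel

cal = DEFAULT_CALIBRATION
print(f"calibration line: v(ml) = {cal.slope} * t(s) + {cal.intercept}")
print(f"fit quality: r^2 = {cal.r_squared}, dispense CV = {cal.cv:.1%}")

ms = cal.solenoid_ms_for_volume(10.0)
v = cal.volume_for_time(ms / 1000.0)
print(f"\n10 ul target -> {ms} ms open time -> {v:.2f} ul actually dispensed")
print("(the shortfall is the cost of never over-dispensing)")

# A fresh calibration from your own burst measurements just needs the
# fitted slope and intercept:
mine = CalibrationModel(slope=0.150, intercept=-0.0010)
print(f"\nwith a weaker valve (slope 0.150): "
      f"10 ul -> {mine.solenoid_ms_for_volume(10.0)} ms")
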