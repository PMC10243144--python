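"""Plate capacity planning for nanofractionation runs.

Shows how many wells one chromatographic run consumes and how many
venoms fit in a four-plate injection sequence at 6 s vs 12 s fraction
resolution.
"""

from venompsc import FractionSchedule, PlateLayout, fraction_to_rt, plan_plate

layout = PlateLayout()  # 384-well, rows A..P, columns 1..24

for resolution in (6.0, 12.0):
    schedule = FractionSchedule(resolution_s=resolution)
    report = plan_plate(layout, schedule, n_plates=4)
    print(f"{resolution:4.0f} s fractions: {report}")

# Each fraction maps to the midpoint of its collection window:
schedule = FractionSchedule(resolution_s=6.0)
print("fraction   1 ->", fraction_to_rt(schedule, 1), "min")
print("fraction 100 ->", fraction_to_rt(schedule, 100), "min")
# At 6 s one run fills 368 wells (one venom per plate); at 12 s two runs
# of 184 wells share a plate, doubling venoms per sequence to 8.
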