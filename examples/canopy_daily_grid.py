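"""Daily canopy photosynthesis vs radiation and canopy size.

Runs the sun/shade canopy model over one 13-h day (diffuse fraction 0.2,
leaves held at 25 degC) for the default C3 crop and the complete C4 route,
across daily global radiation and leaf area index.  Printed values are
daily net canopy photosynthesis (g CO2 m-2 d-1); the route/default ratio
grows with radiation and shrinks with LAI because the routes act mostly on
light-saturated leaves.
"""

from photoroutes.canopy import (
    CanopyState,
    daily_canopy_photosynthesis,
    fig2_style_drivers,
)
from photoroutes.routes import build_route

p0 = build_route(0).params
p6 = build_route(6).params

print("radiation  LAI   A_d(C3)  A_d(complete C4)  ratio")
for rad in (5.0, 15.0, 25.0):
    for lai in (1.0, 3.0, 5.0, 7.0):
        canopy = CanopyState(lai=lai, n_avg=2.3)
        a0 = daily_canopy_photosynthesis(fig2_style_drivers(rad), canopy, p0).a_pot
        a6 = daily_canopy_photosynthesis(fig2_style_drivers(rad), canopy, p6).a_pot
        print(f"{rad:8.0f}  {lai:4.0f}  {a0:8.2f}  {a6:16.2f}  {a6 / a0:5.2f}")
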