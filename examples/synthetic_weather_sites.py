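"""Synthetic weather archetypes and the mid-century climate transform.

Generates three years of daily weather for the tropical, subtropical and
temperate site archetypes and summarizes their growing-season climate;
then applies the 2050 transform (+2 degC, CO2 550 umol mol-1, relative
humidity preserved).  Growing-season warmth must order
tropical > subtropical > temperate.
"""

from photoroutes.weather import (
    DEFAULT_SITES,
    apply_climate_2050,
    generate_weather,
)

for name, make in DEFAULT_SITES.items():
    site = make()
    wx = generate_weather(site, n_years=3, seed=2024)
    start = site.phenology.start_day
    grow = wx[(wx["doy"] >= start) & (wx["doy"] <= start + 120)]
    t_mean = 0.5 * (grow["tmax_C"] + grow["tmin_C"]).mean()
    print(f"{name:12s} lat {site.latitude:5.1f}  emergence doy {start:3d}  "
          f"growing-season T {t_mean:5.1f} C  "
          f"radiation {grow['radiation_MJ'].mean():4.1f} MJ m-2 d-1")

wx = generate_weather(DEFAULT_SITES["tropical"](), 1, seed=2024)
wx50, c_a = apply_climate_2050(wx)
print(f"\n2050 transform: tmax +{(wx50['tmax_C'] - wx['tmax_C']).iloc[0]:.1f} C, "
      f"CO2 {c_a:.0f} umol mol-1, radiation unchanged "
      f"({wx50['radiation_MJ'].equals(wx['radiation_MJ'])})")
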