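"""Reconstruct total PM2.5 from speciated aerosol constituents.

Reanalysis products report surface aerosol as separate constituents (dust,
sea salt, organic carbon, black carbon, sulfate) rather than a single PM2.5
variable. Total PM2.5 is their sum, with sulfate scaled by 132.14/96.06 to
count the ammonium mass of neutralized ammonium sulfate. SO2 arrives as a
mass concentration (kg m^-3) and becomes a ppb mixing ratio via the ideal
gas law at the local air temperature.
"""

import envmeasures as em

spec = em.FieldSpec(
    n_lon=2, n_lat=2, cell_size_deg=0.5, origin_lon=-100.0, origin_lat=35.0,
    n_hours=24,
    variables={v: "ug m^-3" for v in ("DU", "SS", "OC", "BC", "SO4")},
    baseline={"DU": 2.0, "SS": 1.0, "OC": 3.0, "BC": 0.5, "SO4": 4.0},
    seed=0,
)
fields = em.generate_fields(spec)
pm25 = em.reconstruct_pm25(
    fields["DU"], fields["SS"], fields["OC"], fields["BC"], fields["SO4"]
)
print(f"constituents 2 + 1 + 3 + 0.5 ug/m3 and sulfate 4 ug/m3")
print(f"total PM2.5 = {pm25.values[0, 0, 0]:.4f} ug/m3")
print("  (6.5 plus 4 x 132.14/96.06 = 5.5024 of ammonium sulfate)")

gas_spec = em.FieldSpec(
    n_lon=2, n_lat=2, cell_size_deg=0.5, origin_lon=-100.0, origin_lat=35.0,
    n_hours=24, variables={"SO2": "kg m^-3", "T": "K"},
    baseline={"SO2": 1.0e-9, "T": 300.0}, seed=0,
)
gas = em.generate_fields(gas_spec)
so2_ppb = em.so2_mass_to_ppb(gas["SO2"], gas["T"])
print(f"\nSO2 1e-9 kg/m3 at 300 K = {so2_ppb.values[0, 0, 0]:.4f} ppb")
print("  (mass concentration converted to mixing ratio at ambient temperature)")
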