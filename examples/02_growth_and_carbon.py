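"""From woody volume to biomass, carbon and annual uptake rates.

Aboveground biomass (AGB) is volume x wood density (0.34 Mg/m3 for giant
sequoia); carbon is AGB x carbon fraction (0.54).  With a known planting
date, dividing by age gives mean annual rates.
"""

from tlscarbon import (
    GrowthParams,
    StructuralMetrics,
    TreeRecord,
    agb_from_volume,
    growth_rates,
)

# an old avenue tree: 34.9 m3 of wood, planted 1863, scanned 2022
volume = 34.9
agb = agb_from_volume(volume)
print(f"woody volume {volume} m3 -> AGB {agb:.1f} Mg")

record = TreeRecord("benmore", "B_T01", planting_year=1863, scan_year=2022)
metrics = StructuralMetrics(tree_id="B_T01", height=44.3, dbh=1.8,
                            woody_volume=volume)
rates = growth_rates(metrics, record, GrowthParams())
print(f"age {record.age} yr")
print(f"height growth {rates.height_rate:.2f} m/yr")
print(f"DBH growth    {rates.dbh_rate:.2f} cm/yr")
print(f"AGB uptake    {rates.agb_rate:.1f} kg/yr")
print(f"carbon uptake {rates.carbon_rate:.1f} kg/yr")
# The carbon rate is always exactly 0.54 x the AGB rate; both assume
# growth was constant over the tree's lifetime.
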