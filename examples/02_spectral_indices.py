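"""Enumerate generic vegetation-index candidates and evaluate a few.

Lists the 14 index families, counts the band assignments each sensor
admits, and evaluates NDVI-style indices on one simulated plot spectrum.
"""

import uavpheno as u
from uavpheno.indices import FAMILIES, registry_text

print(registry_text())

for sensor in (u.PS, u.P4M):
    n = len(u.enumerate_assignments(list(FAMILIES), sensor))
    print(f"\n{sensor.name} ({len(sensor.bands)} bands): "
          f"{n} ordered band assignments across all families")

# one simulated plot: healthy canopy, 80% cover
plot = u.PlotRecord("demo", "T", "G1", 1,
                    {"LAI": 4.0, "fCover": 0.8, "LCC": 420.0})
(sample,) = u.forward_reflectance([plot], u.P4M, noise_sd=0.0)
print("\nreflectance:", {int(k): round(v, 3)
                         for k, v in sample.reflectance.items()})

for family, bands in [("ND", (840.0, 650.0)), ("SR", (840.0, 650.0)),
                      ("EVI2-like", (730.0, 840.0))]:
    a = u.BandAssignment(family, bands)
    print(f"{a.label():>22}: {u.compute_index(a, sample):.4f}")
# ND(840,650) is the classic NDVI: near 0.6 here, a dense green canopy.
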