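"""Define porosity distribution laws and inspect their radius profiles.

Each law maps height y (μm, 0 = loaded face) to a pore radius A (μm).
The printed table shows A(y) at a few heights plus each law's gradient at
mid-height and its PVPD (percent variation of the pore dimension).
"""

import numpy as np

import fgscaffold as fg

H = 3822.0
laws = {
    "constant": fg.PorosityLaw("constant", (150.0,), 0.0, H),
    "linear": fg.PorosityLaw("linear", (250.0, 100.0), 0.0, H),
    "bilinear": fg.PorosityLaw("bilinear", (250.0, 180.0, 120.0), 0.0, H),
    "trilinear": fg.PorosityLaw("trilinear", (280.0, 220.0, 160.0, 100.0), 0.0, H),
}

heights = np.linspace(0.0, H, 5)
header = "law        " + "".join(f"  A(y={y:5.0f})" for y in heights)
print(header)
for name, law in laws.items():
    radii = "".join(f"  {fg.evaluate_radius(law, y):9.1f}" for y in heights)
    print(f"{name:<11}{radii}")

print("\nmid-height gradient m = dA/dy (μm/μm) and PVPD (%):")
for name, law in laws.items():
    m = fg.gradient(law, H / 2.0)
    print(f"{name:<11}  m = {m:+.5f}   PVPD = {fg.pvpd(law):6.1f} %")

print(
    "\nA negative gradient means pores shrink from the loaded face toward"
    "\nthe clamped face; PVPD = 0 identifies a homogeneous-porosity scaffold."
)
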