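"""Case definitions on the ETDRS severity scale.

Classifies a handful of eyes with the referable-disease (ETDRS >= 35 or DME),
vision-threatening (ETDRS >= 53 or DME) and center-involved-DME (OCT central
subfield > 300 µm) rules.
"""

from drdtrial import ETDRSLevel, classify_cidme, is_drd_positive, is_vtdrd

cases = [
    ("35A", False, None),   # mild nonproliferative retinopathy, no edema
    ("20", False, None),    # microaneurysms only
    ("10", True, 307.0),    # no retinopathy but macular edema on OCT
    ("60", False, 243.0),   # proliferative-range severity
]

print(f"{'ETDRS':>6} {'DME':>5} {'referable DRD':>14} {'vtDRD':>6} {'CIDME':>6}")
for label, dme, thickness in cases:
    level = ETDRSLevel.from_string(label)
    cidme = "n/a" if thickness is None else classify_cidme(thickness)
    print(
        f"{label:>6} {str(dme):>5} {str(is_drd_positive(level, dme)):>14} "
        f"{str(is_vtdrd(level, dme)):>6} {str(cidme):>6}"
    )

# Referable disease needs severity 35+ or any DME; vision-threatening disease
# needs 53+ or DME; CIDME needs thickness strictly above 300 µm (307 -> True).
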