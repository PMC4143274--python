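"""Shared tissue label codes for truth maps and segmentation outputs."""

OUTSIDE = 0
CSF_OTHER = 1
PARENCHYMA = 2  # NAWM + normal-appearing gray matter band not meeting NAWM criteria
WML = 3
ISCHEMIC = 4
NAWM = 5

NAMES = {
    OUTSIDE: "outside",
    CSF_OTHER: "csf_other",
    PARENCHYMA: "parenchyma_band",
    WML: "wml",
    ISCHEMIC: "ischemic",
    NAWM: "nawm",
}
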