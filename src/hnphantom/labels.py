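"""Registered voxel label codes for tissue label maps.

The label volume is an integer grid over the codes below.  Cervical lymph
nodes (CLNs) carry state-specific codes for both the interior (the node
proper) and the perinodal shell, because the dielectric stage assigns
different curves to healthy and metastasized nodes on both regions.
"""

from __future__ import annotations

BACKGROUND = 0
FAT = 1
MUSCLE = 2
MIXED = 3
SKIN = 4
CLN_INTERIOR_HEALTHY = 5
CLN_INTERIOR_METASTASIZED = 6
CLN_SHELL_HEALTHY = 7
CLN_SHELL_METASTASIZED = 8

ALL_CODES = (
    BACKGROUND,
    FAT,
    MUSCLE,
    MIXED,
    SKIN,
    CLN_INTERIOR_HEALTHY,
    CLN_INTERIOR_METASTASIZED,
    CLN_SHELL_HEALTHY,
    CLN_SHELL_METASTASIZED,
)

LABEL_NAMES = {
    BACKGROUND: "background",
    FAT: "fat",
    MUSCLE: "muscle",
    MIXED: "mixed",
    SKIN: "skin",
    CLN_INTERIOR_HEALTHY: "cln_interior_healthy",
    CLN_INTERIOR_METASTASIZED: "cln_interior_metastasized",
    CLN_SHELL_HEALTHY: "cln_shell_healthy",
    CLN_SHELL_METASTASIZED: "cln_shell_metastasized",
}

# MRI-derived (segmented) tissues that take intensity-mapped properties.
SEGMENTED_TISSUES = {"fat": FAT, "muscle": MUSCLE, "mixed": MIXED}

CLN_INTERIOR = {"healthy": CLN_INTERIOR_HEALTHY, "metastasized": CLN_INTERIOR_METASTASIZED}
CLN_SHELL = {"healthy": CLN_SHELL_HEALTHY, "metastasized": CLN_SHELL_METASTASIZED}
CLN_CODES = frozenset(CLN_INTERIOR.values()) | frozenset(CLN_SHELL.values())
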