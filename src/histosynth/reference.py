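"""Published per-k evaluation tables from the KPC-mouse histopathology study
that this pipeline re-implements, used as worked examples for the selection
logic.

``REFERENCE_VALIDITY_TABLE`` lists the five internal cluster-validity
indices for cluster counts 10..16 computed on that study's latent features;
``REFERENCE_SIMILARITY_TABLE`` lists the mean SSIM / MS-SSIM / perceptual
scores of the images generated under each cluster set. In both tables the
14-cluster set is the direction-aware winner on every column.
"""

from __future__ import annotations

from .metrics import SimilarityReport
from .validity import IndexReport

__all__ = [
    "REFERENCE_VALIDITY_TABLE",
    "REFERENCE_SIMILARITY_TABLE",
    "reference_index_reports",
    "reference_similarity_reports",
]

# columns: k, CH, C, Dunn, Hartigan, McClain-Rao
REFERENCE_VALIDITY_TABLE: tuple[tuple[int, float, float, float, float, float], ...] = (
    (10, 2142.54026, 0.12234, 0.00441, 0.65763, 0.54631),
    (11, 2866.86433, 0.10477, 0.00477, 1.05432, 0.49791),
    (12, 1865.81774, 0.12042, 0.00463, 0.72021, 0.55443),
    (13, 2836.22720, 0.09131, 0.00424, 1.22610, 0.46335),
    (14, 3367.74211, 0.07645, 0.00548, 1.47801, 0.41643),
    (15, 2027.82944, 0.10489, 0.00424, 1.04494, 0.51414),
    (16, 2603.28507, 0.08615, 0.00490, 1.36384, 0.45223),
)

# columns: k, SSIM, MS-SSIM, LPIPS
REFERENCE_SIMILARITY_TABLE: tuple[tuple[int, float, float, float], ...] = (
    (10, 0.7814, 0.2138, 0.5008),
    (11, 0.7835, 0.2130, 0.5003),
    (12, 0.7801, 0.2168, 0.5032),
    (13, 0.7865, 0.2161, 0.4987),
    (14, 0.7988, 0.2196, 0.4923),
    (15, 0.7889, 0.2152, 0.4980),
    (16, 0.7908, 0.2186, 0.4939),
)


def reference_index_reports() -> list[IndexReport]:
    return [
        IndexReport(k=k, ch=ch, c_index=c, dunn=d, hartigan=h, mcclain_rao=mr)
        for k, ch, c, d, h, mr in REFERENCE_VALIDITY_TABLE
    ]


def reference_similarity_reports() -> list[SimilarityReport]:
    return [
        SimilarityReport(k=k, ssim_mean=s, ms_ssim_mean=ms, lpips_mean=lp, n_pairs=10000)
        for k, s, ms, lp in REFERENCE_SIMILARITY_TABLE
    ]
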