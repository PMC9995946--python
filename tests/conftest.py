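"""Shared fixtures: small synthetic datasets and FreeSurfer stats fixtures.

Everything is generated programmatically at test time; the FreeSurfer
fixtures are minimal but dialect-faithful stats files written to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sfascreen import Dataset, default_config, generate_cohorts, noise_free_config
from sfascreen.features import DK_REGIONS

SMALL_N = {"CN": 120, "MCI": 120, "Dementia": 120}


@pytest.fixture(scope="session")
def small_config():
    return default_config(n_per_cohort=SMALL_N, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Default-calibrated noisy three-cohort sample, 120 per cohort."""
    return generate_cohorts(small_config)


@pytest.fixture(scope="session")
def noise_free_dataset(small_config):
    return generate_cohorts(noise_free_config(small_config), seed=8)


@pytest.fixture()
def toy_frame():
    """Hand-written three-row subject table in the canonical layout."""
    return pd.DataFrame(
        {
            "subject_id": ["s1", "s2", "s3"],
            "visit_index": [1, 1, 2],
            "age": [70.0, 75.5, 81.0],
            "sex": ["F", "M", "F"],
            "education": [16.0, 12.0, 18.0],
            "cohort": ["CN", "MCI", "Dementia"],
            "MMSE": [29.0, 27.0, 22.0],
            "ADAS13": [8.0, 19.0, 31.0],
            "vol_hippocampus": [0.28, 0.24, 0.19],
            "vol_precuneus": [0.66, 0.61, 0.55],
        }
    )


def make_dataset(frame: pd.DataFrame, feature_names=None) -> Dataset:
    if feature_names is None:
        feature_names = [c for c in frame.columns if c.startswith(("vol_", "thick_", "area_"))]
    return Dataset(frame=frame.reset_index(drop=True), feature_names=list(feature_names))


ASEG_HEADER = """# Title Segmentation Statistics
# generating_program mri_segstats
# Measure BrainSeg, BrainSegVol, Brain Segmentation Volume, 1150000.000000, mm^3
# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total Intracranial Volume, {tiv}, mm^3
# ColHeaders  Index SegId NVoxels Volume_mm3 StructName normMean normStdDev normMin normMax normRange
"""


def write_aseg(path, tiv=1.5e6, rows=None):
    """Write a minimal aseg.stats; rows = [(struct_name, volume_mm3), ...]."""
    if rows is None:
        rows = [("Left-Hippocampus", 4000.0), ("Right-Hippocampus", 4200.0)]
    lines = [ASEG_HEADER.format(tiv=f"{tiv:.6f}")]
    for i, (name, vol) in enumerate(rows, start=1):
        lines.append(f"{i:4d} {10 + i:4d} {int(vol):7d} {vol:10.1f}  {name:<30s} 75.0 10.0 20.0 110.0 90.0\n")
    path.write_text("".join(lines))
    return path


APARC_HEADER = """# Table of FreeSurfer cortical parcellation anatomical statistics
# hemi {hemi}
# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd MeanCurv GausCurv FoldInd CurvInd
"""


def write_aparc(path, hemi="lh", regions=DK_REGIONS, gray_vol=3000.0, thick=2.5, area=1800.0):
    lines = [APARC_HEADER.format(hemi=hemi)]
    for i, region in enumerate(regions):
        lines.append(
            f"{region} {2000 + i} {area + i:.0f} {gray_vol + 10 * i:.0f} "
            f"{thick + 0.01 * i:.3f} 0.50 0.12 0.03 20 2.0\n"
        )
    path.write_text("".join(lines))
    return path
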