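"""Offline cohort checker for a locally downloaded melanoma cohort.

Given a cBioPortal-style clinical table you have downloaded yourself (this
script performs no network access), computes three cohort summaries: the
number of primary-tumor patients, the number of those with disease-free
survival information, and the Kaplan–Meier median overall survival in
months.

Usage:
    python scripts/tcga_check.py --clinical data_clinical.tsv \
        --id-col PATIENT_ID --sample-type-col SAMPLE_TYPE \
        --os-time-col OS_MONTHS --os-status-col OS_STATUS \
        --dfs-time-col DFS_MONTHS --dfs-status-col DFS_STATUS \
        --primary-tag Primary

Status columns may be coded 0/1 or cBioPortal-style ("1:DECEASED",
"0:LIVING", "1:Recurred/Progressed", ...); the leading digit is used.
"""

from __future__ import annotations

import argparse
import json

import numpy as np
import pandas as pd

from sfdkit import km_median


def parse_status(series: pd.Series) -> pd.Series:
    def one(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip()
        return float(s.split(":")[0]) if ":" in s else float(s)

    return series.map(one)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--clinical", required=True)
    ap.add_argument("--id-col", default="PATIENT_ID")
    ap.add_argument("--sample-type-col", default="SAMPLE_TYPE")
    ap.add_argument("--os-time-col", default="OS_MONTHS")
    ap.add_argument("--os-status-col", default="OS_STATUS")
    ap.add_argument("--dfs-time-col", default="DFS_MONTHS")
    ap.add_argument("--dfs-status-col", default="DFS_STATUS")
    ap.add_argument("--primary-tag", default="Primary")
    args = ap.parse_args()

    df = pd.read_csv(args.clinical, sep="\t", comment="#")
    primary = df[df[args.sample_type_col] == args.primary_tag]

    os_time = pd.to_numeric(primary[args.os_time_col], errors="coerce")
    os_event = parse_status(primary[args.os_status_col])
    have_os = os_time.notna() & os_event.notna()

    dfs_time = pd.to_numeric(primary[args.dfs_time_col], errors="coerce")
    dfs_event = parse_status(primary[args.dfs_status_col])
    have_dfs = dfs_time.notna() & dfs_event.notna()

    median = km_median(os_time[have_os].to_numpy(), os_event[have_os].to_numpy())
    print(
        json.dumps(
            {
                "primary_tumor_patients": int(len(primary)),
                "patients_with_dfs": int(have_dfs.sum()),
                "km_median_os_months": median if median is not None else "not reached",
            },
            indent=2,
        )
    )


if __name__ == "__main__":
    main()
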