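"""Patient-level cohort manifests and packaged reference cohorts.

The manifest is the unit of diagnosis and of train/test splitting:
each row is one patient with a binary label (cancer / non-cancer),
an optional tumour type and WHO grade, and demographics.

Two reference cohorts are built in, mirroring the published brain-cancer
triage study design this package emulates:

* ``retrospective_table1`` — the 724-patient retrospective cohort
  (487 cancer across 20 tumour-type rows, 237 non-cancer controls).
* ``prospective_interim`` — the 104-patient prospective interim cohort
  (12 cancer, 92 non-cancer).

Only the published per-row counts are factual; per-patient ages and
sexes are synthesized deterministically to match the reported marginal
summaries and are labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, UsageError

MANIFEST_COLUMNS = [
    "patient_id",
    "cohort",
    "label",
    "tumour_type",
    "who_grade",
    "age",
    "sex",
]

CANCER = "cancer"
NON_CANCER = "non-cancer"

#: Retrospective cohort breakdown: (WHO classification, tumour type, WHO grade, count).
RETROSPECTIVE_TUMOUR_ROWS: list[tuple[str, str, str, int]] = [
    ("Diffuse astrocytic and oligodendroglial tumours", "Glioblastoma multiforme", "IV", 260),
    ("Diffuse astrocytic and oligodendroglial tumours", "Gliosarcoma", "IV", 4),
    ("Diffuse astrocytic and oligodendroglial tumours", "Oligodendroglioma", "II", 11),
    ("Diffuse astrocytic and oligodendroglial tumours", "Diffuse astrocytoma", "II", 23),
    ("Diffuse astrocytic and oligodendroglial tumours", "Anaplastic astrocytoma", "III", 10),
    ("Diffuse astrocytic and oligodendroglial tumours", "Oligoastrocytoma", "II", 3),
    ("Diffuse astrocytic and oligodendroglial tumours", "Glioma", "I", 7),
    ("Other astrocytic tumours", "Pilocytic astrocytoma", "I", 9),
    ("Other astrocytic tumours", "Pleomorphic xanthoastrocytoma", "II", 1),
    ("Tumours of the cranial and paraspinal nerves", "Schwannoma", "I", 14),
    ("Ependymal tumours", "Ependymoma", "II", 6),
    ("Mesenchymal, non-meningothelial tumours", "Haemangiopericytoma", "II/III", 2),
    ("Mesenchymal, non-meningothelial tumours", "Haemanglioblastoma", "I", 1),
    ("Neuronal and mixed neuronal-glial tumours", "Ganglioglioma", "I", 1),
    ("Embryonal tumours", "Medulloblastoma", "IV", 1),
    ("Tumours of the pineal region", "PPTID", "II/III", 1),
    ("Meningiomas", "Meningioma", "I", 46),
    ("Pituitary tumours", "Pituitary adenoma", "", 29),
    ("Lymphomas", "Lymphoma", "", 2),
    ("Metastatic tumours", "Metastasis", "", 56),
]

RETROSPECTIVE_N_CONTROL = 237

#: Prospective interim cohort: tumour type → count among the 12 cancers.
PROSPECTIVE_TUMOUR_COUNTS: list[tuple[str, str, int]] = [
    ("Glioblastoma multiforme", "IV", 4),
    ("Anaplastic astrocytoma", "III", 3),
    ("Oligoastrocytoma", "II", 2),
    ("Medulloblastoma", "IV", 1),
    ("Ependymoma", "II", 1),
    ("Gliosarcoma", "IV", 1),
]

PROSPECTIVE_N_TOTAL = 104


@dataclass
class CohortManifest:
    """Patient-level table of labels, tumour types and demographics."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"manifest is missing mandatory columns: {missing}")
        ids = self.frame["patient_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise UsageError(f"duplicate patient ids in manifest: {dupes}")
        labels = set(self.frame["label"].unique())
        unknown = labels - {CANCER, NON_CANCER}
        if unknown:
            raise UsageError(f"unknown labels in manifest: {sorted(unknown)}")
        tt = self.frame["tumour_type"].fillna("")
        bad = self.frame[(self.frame["label"] == NON_CANCER) & (tt != "")]
        if len(bad):
            raise UsageError(
                f"non-cancer patients must have empty tumour_type: {list(bad['patient_id'])[:5]}"
            )
        bad = self.frame[(self.frame["label"] == CANCER) & (tt == "")]
        if len(bad):
            raise UsageError(
                f"cancer patients must carry a tumour_type: {list(bad['patient_id'])[:5]}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.frame["patient_id"])

    @property
    def labels(self) -> dict[str, str]:
        return dict(zip(self.frame["patient_id"], self.frame["label"]))

    @property
    def n_cancer(self) -> int:
        return int((self.frame["label"] == CANCER).sum())

    @property
    def n_control(self) -> int:
        return int((self.frame["label"] == NON_CANCER).sum())

    def ids_with_label(self, label: str) -> list[str]:
        return list(self.frame.loc[self.frame["label"] == label, "patient_id"])

    def tumour_type_counts(self) -> pd.Series:
        cancers = self.frame[self.frame["label"] == CANCER]
        return cancers["tumour_type"].value_counts()


def _synthesize_demographics(
    n: int,
    rng: np.random.Generator,
    age_mean: float,
    age_sd: float,
    age_range: tuple[int, int],
    n_male: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stand-in ages/sexes matching reported marginal summaries."""
    ages = np.clip(
        np.round(rng.normal(age_mean, age_sd, size=n)), age_range[0], age_range[1]
    ).astype(int)
    sexes = np.array(["M"] * min(n_male, n) + ["F"] * max(n - n_male, 0))
    rng.shuffle(sexes)
    return ages, sexes


def retrospective_table1() -> CohortManifest:
    """The 724-patient retrospective reference cohort.

    Tumour-type counts, WHO grades and the control count are the
    published values; individual ages/sexes are synthetic, drawn with a
    fixed seed to match the reported marginals (cancer: 280 M / 207 F,
    ages 21–96, mean 61; non-cancer: 149 M / 84 F recorded, ages 19–69,
    mean 35 — the published sex counts for controls sum to 233 of 237;
    the 4 unaccounted patients are carried with empty sex).
    """
    rng = np.random.default_rng(20191008)
    rows: list[dict] = []
    idx = 1
    for _who_class, tumour_type, grade, count in RETROSPECTIVE_TUMOUR_ROWS:
        for _ in range(count):
            rows.append(
                {
                    "patient_id": f"R{idx:04d}",
                    "cohort": "retrospective",
                    "label": CANCER,
                    "tumour_type": tumour_type,
                    "who_grade": grade,
                }
            )
            idx += 1
    n_cancer = len(rows)
    ages_c, sexes_c = _synthesize_demographics(
        n_cancer, rng, age_mean=61, age_sd=14, age_range=(21, 96), n_male=280
    )
    for row, age, sex in zip(rows, ages_c, sexes_c):
        row["age"] = age
        row["sex"] = sex
    ages_n, sexes_n = _synthesize_demographics(
        RETROSPECTIVE_N_CONTROL, rng, age_mean=35, age_sd=10, age_range=(19, 69), n_male=149
    )
    # 149 M + 84 F = 233 reported sexes for 237 controls; leave the rest blank.
    sexes_n = np.concatenate([sexes_n[:233], np.array([""] * (RETROSPECTIVE_N_CONTROL - 233))])
    for age, sex in zip(ages_n, sexes_n):
        rows.append(
            {
                "patient_id": f"R{idx:04d}",
                "cohort": "retrospective",
                "label": NON_CANCER,
                "tumour_type": "",
                "who_grade": "",
                "age": age,
                "sex": sex,
            }
        )
        idx += 1
    return CohortManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


def prospective_interim() -> CohortManifest:
    """The 104-patient prospective interim reference cohort (12 cancer, 92 non-cancer)."""
    rng = np.random.default_rng(20191009)
    rows: list[dict] = []
    idx = 1
    for tumour_type, grade, count in PROSPECTIVE_TUMOUR_COUNTS:
        for _ in range(count):
            rows.append(
                {
                    "patient_id": f"P{idx:03d}",
                    "cohort": "prospective",
                    "label": CANCER,
                    "tumour_type": tumour_type,
                    "who_grade": grade,
                }
            )
            idx += 1
    n_cancer = len(rows)
    n_control = PROSPECTIVE_N_TOTAL - n_cancer
    ages_c, sexes_c = _synthesize_demographics(
        n_cancer, rng, age_mean=61, age_sd=14, age_range=(21, 96), n_male=n_cancer // 2
    )
    for row, age, sex in zip(rows, ages_c, sexes_c):
        row["age"] = age
        row["sex"] = sex
    ages_n, sexes_n = _synthesize_demographics(
        n_control, rng, age_mean=50, age_sd=15, age_range=(18, 90), n_male=n_control // 2
    )
    for age, sex in zip(ages_n, sexes_n):
        rows.append(
            {
                "patient_id": f"P{idx:03d}",
                "cohort": "prospective",
                "label": NON_CANCER,
                "tumour_type": "",
                "who_grade": "",
                "age": age,
                "sex": sex,
            }
        )
        idx += 1
    return CohortManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


_FIXTURES = {
    "retrospective_table1": retrospective_table1,
    "prospective_interim": prospective_interim,
}


def builtin_fixture(name: str) -> CohortManifest:
    """Return a packaged reference cohort by name.

    Valid names: ``retrospective_table1``, ``prospective_interim``.
    """
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise UsageError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return factory()
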