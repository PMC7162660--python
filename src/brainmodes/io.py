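"""TSV (and minimal VCF) input/output for every pipeline artefact.

All tabular formats are tab-separated with a header row and a subject-id
first column; missing values are written as empty fields and read as either
empty fields or "NA".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfoundTable, GenotypePanel, IDPMatrix, NIDPTable

__all__ = [
    "read_idp_matrix",
    "write_idp_matrix",
    "read_confounds",
    "write_confounds",
    "read_nidps",
    "write_nidps",
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
]

_NA = ["", "NA"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=_NA, keep_default_na=False)


def write_idp_matrix(matrix: IDPMatrix, values_path: str | Path, meta_path: str | Path) -> None:
    matrix.to_frame().to_csv(values_path, sep="\t", na_rep="", index_label="subject_id")
    pd.DataFrame(
        {"idp_id": matrix.idp_ids, "modality_group": matrix.modality_groups}
    ).to_csv(meta_path, sep="\t", index=False)


def read_idp_matrix(values_path: str | Path, meta_path: str | Path) -> IDPMatrix:
    df = _read_tsv(values_path)
    meta = pd.read_csv(meta_path, sep="\t")
    groups = dict(zip(meta["idp_id"].astype(str), meta["modality_group"].astype(str)))
    return IDPMatrix.from_frame(df, groups)


def write_confounds(confounds: ConfoundTable, path: str | Path) -> None:
    frame = confounds.frame.copy()
    # age-related flag carried in the header as a column-name suffix-free
    # companion row would be fragile; a sidecar list keeps the TSV plain
    frame.to_csv(path, sep="\t", index_label="subject_id")
    side = Path(path).with_suffix(Path(path).suffix + ".age_related")
    side.write_text("\n".join(confounds.age_related) + ("\n" if confounds.age_related else ""))


def read_confounds(path: str | Path, age_related: list[str] | None = None) -> ConfoundTable:
    frame = _read_tsv(path)
    if age_related is None:
        side = Path(path).with_suffix(Path(path).suffix + ".age_related")
        age_related = (
            [l for l in side.read_text().splitlines() if l] if side.exists() else []
        )
    return ConfoundTable(frame, age_related=age_related)


def write_nidps(nidps: NIDPTable, values_path: str | Path, groups_path: str | Path) -> None:
    nidps.frame.to_csv(values_path, sep="\t", na_rep="", index_label="subject_id")
    pd.DataFrame(
        {"variable_id": list(nidps.groups), "variable_group": list(nidps.groups.values())}
    ).to_csv(groups_path, sep="\t", index=False)


def read_nidps(values_path: str | Path, groups_path: str | Path) -> NIDPTable:
    frame = _read_tsv(values_path)
    meta = pd.read_csv(groups_path, sep="\t")
    groups = dict(zip(meta["variable_id"].astype(str), meta["variable_group"].astype(str)))
    return NIDPTable(frame, groups)


def write_genotypes(
    panel: GenotypePanel, dosage_path: str | Path, map_path: str | Path
) -> None:
    pd.DataFrame(
        panel.dosages, index=panel.subject_ids, columns=panel.variants["variant_id"]
    ).to_csv(dosage_path, sep="\t", index_label="subject_id")
    panel.variants.to_csv(map_path, sep="\t", index=False)


def read_genotypes(dosage_path: str | Path, map_path: str | Path) -> GenotypePanel:
    df = _read_tsv(dosage_path)
    variants = pd.read_csv(map_path, sep="\t")
    if list(df.columns) != list(variants["variant_id"].astype(str)):
        raise ValueError("dosage columns and variant map disagree")
    return GenotypePanel(df.to_numpy(float), variants, [str(s) for s in df.index])


def read_vcf(path: str | Path, cm_per_mb: float = 1.0) -> GenotypePanel:
    """Minimal VCF reader (uncompressed; uses DS if present, else GT).

    Genetic positions are laid on a uniform ``cm_per_mb`` map, MAF and
    genotype counts are derived from the parsed genotypes (dosages are
    rounded to the nearest genotype for counting), and the info score
    defaults to 1.0 when no INFO/INFO field is present.
    """
    import pysam

    ids, chroms, pos, dos_rows, infos = [], [], [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            per_sample = []
            for s in samples:
                fmt = rec.samples[s]
                if "DS" in fmt and fmt["DS"] is not None:
                    per_sample.append(float(fmt["DS"]))
                elif "GT" in fmt and fmt["GT"] is not None:
                    per_sample.append(float(sum(1 for a in fmt["GT"] if a == 1)))
                else:
                    raise ValueError(f"variant {rec.id}: neither DS nor GT present")
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            chroms.append(rec.chrom)
            pos.append(rec.pos)  # 1-based, as in VCF
            dos_rows.append(np.asarray(per_sample))
            try:
                infos.append(float(rec.info["INFO"]))
            except (KeyError, ValueError):  # INFO score absent from header
                infos.append(1.0)
    dosages = np.array(dos_rows).T if dos_rows else np.empty((len(samples), 0))
    hard = np.rint(dosages)
    freq = dosages.mean(axis=0) / 2.0 if dosages.size else np.array([])
    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chroms,
            "pos_bp": pos,
            "pos_cm": np.asarray(pos, float) / 1e6 * cm_per_mb,
            "maf": np.minimum(freq, 1 - freq),
            "info": infos,
            "n_homref": (hard == 0).sum(axis=0),
            "n_het": (hard == 1).sum(axis=0),
            "n_homalt": (hard == 2).sum(axis=0),
        }
    )
    return GenotypePanel(dosages, variants, samples)
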