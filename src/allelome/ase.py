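"""Allele-specific expression tests on maternal/paternal count pairs.

Per-phase allelic bias is a Wald test on the allele coefficient of an NB
GLM; phase-dependent bias is a likelihood-ratio test on the phase x allele
interaction against the leaf-explant baseline. Size factors are computed
jointly across all alleles per sample so that normalisation cannot distort
the within-pair allelic ratio.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glm import LN2, NBFit, bh_adjust, fit_nb_glm, lrt, mom_dispersion, size_factors

ASE_LFC_THRESHOLD = 1.0
ASE_FDR_THRESHOLD = 0.05


class AlleleCounts:
    """Allele-resolved counts: two gene x sample frames sharing sample layout.

    ``samples`` is a frame with columns sample_id, phase, replicate applying
    to both allele matrices; maternal/paternal frames are indexed by pair id.
    """

    def __init__(
        self,
        maternal: pd.DataFrame,
        paternal: pd.DataFrame,
        samples: pd.DataFrame,
    ) -> None:
        if not maternal.index.equals(paternal.index):
            raise ValueError("maternal and paternal frames must share pair index")
        if not maternal.columns.equals(paternal.columns):
            raise ValueError("maternal and paternal frames must share sample columns")
        if (maternal.to_numpy() < 0).any() or (paternal.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.maternal = maternal
        self.paternal = paternal
        self.samples = (
            samples.set_index("sample_id")
            .loc[maternal.columns]
            .rename_axis("sample_id")
            .reset_index()
        )

    @property
    def pairs(self) -> pd.Index:
        return self.maternal.index

    def phase_columns(self, phase: str) -> list[str]:
        return self.samples.loc[self.samples["phase"] == phase, "sample_id"].tolist()

    def joint_size_factors(self) -> np.ndarray:
        stacked = pd.concat([self.maternal, self.paternal], axis=0)
        return size_factors(stacked)


def test_ase_per_phase(
    counts: AlleleCounts,
    phase: str,
    lfc_threshold: float = ASE_LFC_THRESHOLD,
    fdr_threshold: float = ASE_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Per-pair Wald test of maternal vs paternal counts within one phase.

    log2FC is maternal over paternal. Bias calls need |log2FC| > 1 and
    FDR < 0.05 (BH across pairs within the phase). All-zero pairs excluded.
    """
    cols = counts.phase_columns(phase)
    if len(cols) < 2:
        raise ValueError(f"phase {phase}: need >= 2 replicates")
    sf_all = counts.joint_size_factors()
    sf = sf_all[[list(counts.maternal.columns).index(c) for c in cols]]
    mat = counts.maternal[cols].to_numpy(dtype=float)
    pat = counts.paternal[cols].to_numpy(dtype=float)
    n = len(cols)
    # observations: maternal replicates then paternal replicates
    X = np.column_stack([np.ones(2 * n), np.r_[np.ones(n), np.zeros(n)]])
    offset = np.log(np.r_[sf, sf])
    groups = np.r_[np.zeros(n), np.ones(n)]
    rows = []
    for i, pair in enumerate(counts.pairs):
        y = np.r_[mat[i], pat[i]]
        if not np.any(y > 0):
            continue
        alpha = mom_dispersion(y, np.r_[sf, sf], groups)
        fit = fit_nb_glm(y, X, alpha, offset=offset)
        lfc = float(fit.beta[1]) / LN2
        _, p = fit.wald(1)
        rows.append({"pair_id": pair, "phase": phase, "log2FC": lfc, "p": p})
    out = pd.DataFrame(rows, columns=["pair_id", "phase", "log2FC", "p"])
    out["FDR"] = bh_adjust(out["p"].to_numpy())
    biased = (out["log2FC"].abs() > lfc_threshold) & (out["FDR"] < fdr_threshold)
    out["bias"] = np.where(
        biased & (out["log2FC"] > 0), "maternal", np.where(biased, "paternal", "none")
    )
    return out


def test_phase_dependent_ase(
    counts: AlleleCounts,
    phases: Sequence[str] | None = None,
    baseline: str = "LE",
    lfc_threshold: float = ASE_LFC_THRESHOLD,
    fdr_threshold: float = ASE_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Interaction (phase x allele) LRT of each phase against the baseline.

    For each pair and contrast the counts of {baseline, phase} are fitted
    with phase + allele + phase:allele and compared with the no-interaction
    model; the interaction effect is log2FC(phase) - log2FC(baseline). BH is
    applied across pairs x contrasts; flags need |effect| > 1 and FDR < 0.05.
    """
    all_phases = list(dict.fromkeys(counts.samples["phase"]))
    if baseline not in all_phases:
        raise ValueError(f"baseline phase {baseline!r} missing from samples")
    if phases is None:
        phases = [p for p in all_phases if p != baseline]
    sf_all = counts.joint_size_factors()
    col_index = {c: i for i, c in enumerate(counts.maternal.columns)}
    rows = []
    for phase in phases:
        base_cols = counts.phase_columns(baseline)
        phase_cols = counts.phase_columns(phase)
        cols = base_cols + phase_cols
        nb, np_ = len(base_cols), len(phase_cols)
        sf = sf_all[[col_index[c] for c in cols]]
        offset = np.log(np.r_[sf, sf])
        is_phase = np.r_[np.zeros(nb), np.ones(np_)]
        is_mat = np.r_[np.ones(nb + np_), np.zeros(nb + np_)]
        ph2 = np.r_[is_phase, is_phase]
        X_full = np.column_stack([np.ones(2 * (nb + np_)), ph2, is_mat, ph2 * is_mat])
        X_red = X_full[:, :3]
        mat = counts.maternal[cols].to_numpy(dtype=float)
        pat = counts.paternal[cols].to_numpy(dtype=float)
        groups = np.r_[is_phase, is_phase + 2]  # 4 mean groups
        for i, pair in enumerate(counts.pairs):
            y = np.r_[mat[i], pat[i]]
            if not np.any(y > 0):
                continue
            alpha = mom_dispersion(y, np.r_[sf, sf], groups)
            full = fit_nb_glm(y, X_full, alpha, offset=offset)
            red = fit_nb_glm(y, X_red, alpha, offset=offset)
            effect = float(full.beta[3]) / LN2
            p = lrt(full, red, df=1)
            rows.append(
                {"pair_id": pair, "contrast": f"{phase}_vs_{baseline}", "phase": phase,
                 "interaction_log2FC": effect, "p": p}
            )
    out = pd.DataFrame(rows, columns=["pair_id", "contrast", "phase", "interaction_log2FC", "p"])
    out["FDR"] = bh_adjust(out["p"].to_numpy())
    out["phase_dependent"] = (out["interaction_log2FC"].abs() > lfc_threshold) & (
        out["FDR"] < fdr_threshold
    )
    return out


def classify_consistency(per_phase: pd.DataFrame) -> pd.DataFrame:
    """Per-pair cross-phase bias class.

    consistent_maternal/paternal: same non-none call in all phases;
    shifting: both maternal and paternal calls occur; phase_specific: biased
    in some but not all phases, single direction; unbiased: never biased.
    """
    rows = []
    for pair, sub in per_phase.groupby("pair_id", sort=False):
        calls = sub["bias"].tolist()
        kinds = set(calls) - {"none"}
        if not kinds:
            label = "unbiased"
        elif len(kinds) == 2:
            label = "shifting"
        elif "none" not in calls:
            label = f"consistent_{kinds.pop()}"
        else:
            label = "phase_specific"
        rows.append({"pair_id": pair, "consistency": label})
    return pd.DataFrame(rows, columns=["pair_id", "consistency"])


def allele_pca(log_tpm: pd.DataFrame, parent_of: Mapping[str, str]) -> pd.DataFrame:
    """Centred PCA scoring alleles on their log2(TPM+1) sample profiles.

    ``log_tpm`` is alleles x samples; rows are observations. Returns scores
    for the first two components plus the parent-of-origin label and the
    explained-variance ratios (as frame attrs).
    """
    from sklearn.decomposition import PCA

    if log_tpm.shape[0] < 2:
        raise ValueError("need at least 2 alleles")
    mat = log_tpm.to_numpy(dtype=float)
    pca = PCA(n_components=min(2, min(mat.shape) - 1) or 1)
    scores = pca.fit_transform(mat - mat.mean(axis=0, keepdims=True))
    out = pd.DataFrame(
        scores[:, :2] if scores.shape[1] >= 2 else np.c_[scores, np.zeros(len(mat))],
        index=log_tpm.index,
        columns=["PC1", "PC2"],
    )
    out["parent"] = [parent_of.get(a, "unknown") for a in log_tpm.index]
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out
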