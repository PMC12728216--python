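"""Fingerprint featurization of metal complexes and SVM activity modelling.

The published 598-bit metal-complex fingerprint is defined elsewhere; this
module ships a width-compatible emulation with a fixed block layout —
scaffold-identity bits, donor-environment bits and hashed ligand-substructure
bits — behind a versioned :class:`FingerprintConfig`, so an exact bit
definition can be dropped in later without touching the model code.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InputError, UnsupportedKernelError
from .library_design import ComplexSpec
from .screening_analytics import ACTIVITY_CUTOFF_UM, MICResult, binarize_activity

N_BITS = 598
SCAFFOLD_IDS = ("IrCN", "IrCp*", "RuCy", "Re(CO)3", "Mn(CO)3")


@dataclass(frozen=True)
class FingerprintConfig:
    n_bits: int = N_BITS
    scaffold_bits: int = 8       # one-hot over known scaffolds
    donor_bits: int = 8          # ligand class / charge environment
    radius: int = 2              # substructure radius when a structure is given
    hash_seed: int = 0
    version: str = "emulated-1"

    @property
    def ligand_bits(self) -> int:
        return self.n_bits - self.scaffold_bits - self.donor_bits


def feature_names(config: FingerprintConfig | None = None) -> list[str]:
    config = config or FingerprintConfig()
    names = [f"scaffold:{s}" for s in SCAFFOLD_IDS]
    names += [f"scaffold:reserved{i}" for i in range(len(SCAFFOLD_IDS), config.scaffold_bits)]
    names += [f"donor:{n}" for n in ("Tz-4-P", "Tz-1-MP", "cationic")]
    names += [f"donor:reserved{i}" for i in range(3, config.donor_bits)]
    names += [f"ligand_bit:{i:04d}" for i in range(config.ligand_bits)]
    return names


def _stable_hash(token: str, seed: int, modulus: int) -> int:
    digest = hashlib.sha256(f"{seed}:{token}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % modulus


def _ligand_tokens(spec: ComplexSpec, smiles: str | None, radius: int) -> list[str]:
    if smiles:
        try:
            from rdkit import Chem
            from rdkit.Chem import rdFingerprintGenerator
        except ImportError:
            smiles = None
        else:
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise InputError(f"unparseable structure for {spec.id}: {smiles!r}")
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=2048)
            fp = gen.GetSparseCountFingerprint(mol)
            return [f"env:{k}" for k in sorted(fp.GetNonzeroElements())]
    # formula-only fallback: element-count tokens plus the ligand id tokens
    tokens = [f"elem:{el}:{n}" for el, n in spec.formula.items()]
    tokens.append(f"ligand:{spec.ligand_id}")
    return tokens


def featurize(
    spec: ComplexSpec,
    config: FingerprintConfig | None = None,
    smiles: str | None = None,
) -> np.ndarray:
    """Deterministic 598-bit vector for a complex.

    Scaffold block: one-hot scaffold identity. Donor block: ligand class and
    charge environment. Ligand block: substructure environments (from the
    structure when available, otherwise composition tokens) hashed into the
    remaining bits.
    """
    config = config or FingerprintConfig()
    bits = np.zeros(config.n_bits, dtype=np.int8)
    if spec.scaffold_id in SCAFFOLD_IDS:
        bits[SCAFFOLD_IDS.index(spec.scaffold_id)] = 1
    donor0 = config.scaffold_bits
    if spec.ligand_class == "Tz-4-P":
        bits[donor0] = 1
    elif spec.ligand_class == "Tz-1-MP":
        bits[donor0 + 1] = 1
    if spec.charge > 0:
        bits[donor0 + 2] = 1
    lig0 = config.scaffold_bits + config.donor_bits
    for token in _ligand_tokens(spec, smiles, config.radius):
        bits[lig0 + _stable_hash(token, config.hash_seed, config.ligand_bits)] = 1
    return bits


def make_labels(mic_table: Sequence[tuple[str, MICResult]],
                cutoff: float = ACTIVITY_CUTOFF_UM) -> dict[str, int]:
    """compound id -> binary activity label (1 iff MIC <= cutoff)."""
    return {cid: binarize_activity(mic, cutoff) for cid, mic in mic_table}


# ---------------------------------------------------------------------------
# cross-validated SVM
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    n_folds: int
    seed: int
    auc: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    fold_assignment: np.ndarray  # fold index per sample

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = getattr(self, metric)
        return float(np.mean(vals)), float(np.std(vals, ddof=0))

    def render(self, metric: str) -> str:
        m, s = self.mean_sd(metric)
        return f"{m:.2f} ± {s:.2f}"

    def summary(self) -> dict[str, str]:
        return {m: self.render(m) for m in ("auc", "precision", "recall", "f1")}


def cv_train_svm(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
) -> tuple[CVReport, SVC]:
    """Stratified k-fold CV of an SVM; returns the report and a final model
    refit on the full data (for feature inspection)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < k or n_neg < k:
        raise InputError(f"need >= {k} samples of each class (have {n_pos}/{n_neg})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs, precs, recs, f1s = [], [], [], []
    assignment = np.full(y.shape, -1, dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        assignment[te] = fold
        model = SVC(kernel=kernel, C=C)
        model.fit(X[tr], y[tr])
        score = model.decision_function(X[te])
        pred = model.predict(X[te])
        aucs.append(roc_auc_score(y[te], score))
        precs.append(precision_score(y[te], pred, zero_division=0))
        recs.append(recall_score(y[te], pred, zero_division=0))
        f1s.append(f1_score(y[te], pred, zero_division=0))
    final = SVC(kernel=kernel, C=C)
    final.fit(X, y)
    report = CVReport(
        n_folds=k, seed=seed,
        auc=np.asarray(aucs), precision=np.asarray(precs),
        recall=np.asarray(recs), f1=np.asarray(f1s),
        fold_assignment=assignment,
    )
    return report, final


def feature_importance(model: SVC, names: Sequence[str]) -> list[tuple[str, float]]:
    """Features ranked by |w| of the linear decision function, descending.

    Positive weights push toward the active class. The weight vector is only
    recoverable for a linear kernel (w = sum_i alpha_i y_i x_i).
    """
    if model.kernel != "linear":
        raise UnsupportedKernelError(
            f"support-vector weights undefined for kernel={model.kernel!r}"
        )
    w = np.asarray(model.coef_).ravel()
    if len(names) != w.size:
        raise InputError("feature-name count does not match weight vector")
    ranked = sorted(zip(names, w.tolist()), key=lambda p: abs(p[1]), reverse=True)
    return ranked


# ---------------------------------------------------------------------------
# descriptor correlations
# ---------------------------------------------------------------------------

DESCRIPTOR_PAIRS = (
    ("rt_min", "clogp"),
    ("mw", "activity"),
    ("mw", "toxicity_pct"),
    ("fsp3", "activity"),
)


def crude_clogp(formula) -> float:
    """Very rough atom-contribution lipophilicity proxy (documented as such);
    prefer an externally supplied cLogP column when available."""
    contrib = {"C": 0.36, "H": 0.12, "N": -0.60, "O": -0.41, "S": 0.25,
               "F": 0.22, "Cl": 0.65, "Br": 0.85, "I": 1.05, "P": -0.45}
    return float(sum(contrib.get(el, 0.0) * n for el, n in dict(formula).items()))


def descriptor_correlations(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DESCRIPTOR_PAIRS,
) -> pd.DataFrame:
    """Pearson + Spearman coefficients for declared descriptor pairs.

    Constant columns are flagged (``constant-column``) and yield no
    coefficient; pairs whose columns are absent are skipped.
    """
    if len(table) < 3:
        raise InputError("need at least 3 rows")
    rows = []
    for x, y in pairs:
        if x not in table.columns or y not in table.columns:
            continue
        sub = table[[x, y]].dropna()
        xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
        if len(sub) < 3 or np.ptp(xv) == 0 or np.ptp(yv) == 0:
            rows.append({"x": x, "y": y, "pearson_r": np.nan, "spearman_rho": np.nan,
                         "n": len(sub), "flag": "constant-column"})
            continue
        pear = stats.pearsonr(xv, yv)
        spear = stats.spearmanr(xv, yv)
        rows.append({"x": x, "y": y, "pearson_r": float(pear.statistic),
                     "spearman_rho": float(spear.statistic), "n": len(sub), "flag": ""})
    return pd.DataFrame(rows)


def group_summaries(table: pd.DataFrame, by: str = "activity") -> pd.DataFrame:
    """Mean descriptor values per activity group (active vs inactive)."""
    numeric = table.select_dtypes("number").columns
    return table.groupby(by)[[c for c in numeric if c != by]].mean()
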