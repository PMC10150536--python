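"""The read-level error model.

A feed-forward softmax network predicts, for one read position, the
probability of observing each of the four alleles given the read-level
features and the trinucleotide context.  Because reference-matching
positions are downsampled during training (fraction beta), raw predictions
live in the reweighted distribution; :func:`rescale_probabilities` applies
the analytic prior-shift correction (multiply the downsampled class's
probability by 1/beta, renormalise) before any error rate is derived.

Conditional error rates used by the calling layer:

    e(R->M) = P(X=M | D) / (P(X=R | D) + P(X=M | D))

evaluated with the context centred on the reference base, and e(M->R)
evaluated from a second forward pass with the central context base replaced
by the alternative allele (the only model input that encodes the true base).
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import TRINUCLEOTIDES, FeatureSchema, prepare_design
from .nn import SoftmaxMLP, TrainConfig
from .training import TrainingTable, train_validation_split

ALLELES = ("A", "C", "G", "T")
ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}

ARTIFACT_FORMAT = "plasmavar-error-model/1"


@dataclass
class ErrorModelArtifact:
    """Trained network + schema + the sampling fraction needed for rescaling."""

    schema: FeatureSchema
    model: SoftmaxMLP
    beta: float
    hidden_layout: tuple[int, ...] = (128, 64, 32)
    training_meta: dict = field(default_factory=dict)

    def predict_raw(self, df: pd.DataFrame,
                    chunk_size: int = 200_000) -> np.ndarray:
        """Forward pass in the downsampled training distribution, (n, 4).

        Chunked so multi-million-row tables do not materialise full hidden
        activations.
        """
        dense, tnc = prepare_design(df, self.schema)
        out = np.empty((len(dense), 4))
        for start in range(0, len(dense), chunk_size):
            sl = slice(start, start + chunk_size)
            out[sl] = self.model.forward(
                dense[sl], None if tnc is None else tnc[sl])
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "format": ARTIFACT_FORMAT,
            "schema": self.schema.to_dict(),
            "beta": self.beta,
            "hidden_layout": list(self.hidden_layout),
            "training_meta": self.training_meta,
            "model": self.model.to_jsonable(),
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("model.json", json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ErrorModelArtifact":
        with zipfile.ZipFile(path) as zf:
            payload = json.loads(zf.read("model.json"))
        if payload.get("format") != ARTIFACT_FORMAT:
            raise ValueError(f"unrecognised artifact format: {payload.get('format')}")
        return cls(schema=FeatureSchema.from_dict(payload["schema"]),
                   model=SoftmaxMLP.from_jsonable(payload["model"]),
                   beta=float(payload["beta"]),
                   hidden_layout=tuple(payload["hidden_layout"]),
                   training_meta=payload["training_meta"])


def build_network(schema: FeatureSchema, hidden_layout=(128, 64, 32),
                  embed_dim: int | None = None, seed: int = 0) -> SoftmaxMLP:
    """Untrained network matching a schema (input width checked by encoding)."""
    if embed_dim is not None and embed_dim != schema.embed_dim:
        schema = FeatureSchema(numeric=schema.numeric,
                               numeric_stats=schema.numeric_stats,
                               categorical=schema.categorical,
                               embed_trinucleotide=schema.embed_trinucleotide,
                               embed_dim=embed_dim)
    return SoftmaxMLP(
        dense_width=schema.dense_width,
        hidden_layout=hidden_layout,
        embed_vocab=len(TRINUCLEOTIDES) if schema.embed_trinucleotide else 0,
        embed_dim=schema.embed_dim,
        seed=seed,
    )


def train_error_model(table: TrainingTable,
                      schema: FeatureSchema | None = None,
                      config: TrainConfig | None = None,
                      seed: int = 0,
                      val_fraction: float = 0.2) -> ErrorModelArtifact:
    """Fit the network by minimising the observed-allele NLL.

    The train/validation split is by sample identifier when possible; early
    stopping monitors validation NLL.  Fully reproducible for a fixed seed.
    """
    if len(table.df) == 0:
        raise ValueError("empty training table")
    cfg = config or TrainConfig()
    if schema is None:
        schema = FeatureSchema.from_table(table.df)
    df = table.df
    y = df["obs_allele"].map(ALLELE_INDEX).to_numpy(dtype=np.int64)
    if len(np.unique(y)) == 1:
        import warnings
        warnings.warn("single-class training table; model will be near-degenerate")
    dense, tnc = prepare_design(df, schema)
    tr_idx, va_idx = train_validation_split(table, val_fraction, seed)
    model = build_network(schema, cfg.hidden_layout, seed=seed)
    hist = model.fit(
        dense[tr_idx], None if tnc is None else tnc[tr_idx], y[tr_idx],
        X_val=dense[va_idx], tnc_val=None if tnc is None else tnc[va_idx],
        y_val=y[va_idx], config=cfg, seed=seed + 1,
    )
    meta = {"seed": seed, "epochs": hist["epochs"],
            "initial_nll": hist["initial_nll"],
            "final_train_nll": hist["final_train_nll"],
            "final_val_nll": hist["final_val_nll"],
            "n_train": int(len(tr_idx)), "n_val": int(len(va_idx))}
    return ErrorModelArtifact(schema=schema, model=model,
                              beta=table.match_sampling_fraction,
                              hidden_layout=tuple(cfg.hidden_layout),
                              training_meta=meta)


def rescale_probabilities(probs: np.ndarray, central_base: np.ndarray | str,
                          beta: float) -> np.ndarray:
    """Undo match downsampling: multiply the central-base probability by
    1/beta and renormalise each row.  Identity when beta == 1."""
    if not 0 < beta <= 1:
        raise ValueError("artifact is missing a valid sampling fraction beta")
    probs = np.asarray(probs, dtype=float)
    if isinstance(central_base, str):
        idx = np.full(len(probs), ALLELE_INDEX[central_base])
    else:
        idx = np.asarray([ALLELE_INDEX[b] for b in central_base])
    w = np.ones_like(probs)
    w[np.arange(len(probs)), idx] = 1.0 / beta
    out = probs * w
    return out / out.sum(axis=1, keepdims=True)


def _substitute_central(tnc: pd.Series, base: str) -> pd.Series:
    return tnc.str[0] + base + tnc.str[2]


def predict_error_rates(artifact: ErrorModelArtifact, df: pd.DataFrame,
                        ref_allele: str, alt_allele: str
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-read conditional error-rate pairs (e(R->M), e(M->R)).

    ``df`` holds one row per read covering the site, with the trinucleotide
    centred on the reference base.  The reverse rate comes from a
    counterfactual pass with the central context base set to the alternative
    allele.
    """
    if ref_allele == alt_allele:
        raise ValueError("ref and alt alleles must differ")
    r = ALLELE_INDEX[ref_allele]
    m = ALLELE_INDEX[alt_allele]

    p_ref_ctx = rescale_probabilities(artifact.predict_raw(df),
                                      ref_allele, artifact.beta)
    e_rm = p_ref_ctx[:, m] / (p_ref_ctx[:, r] + p_ref_ctx[:, m])

    df_alt = df.copy()
    df_alt["trinucleotide"] = _substitute_central(df["trinucleotide"], alt_allele)
    p_alt_ctx = rescale_probabilities(artifact.predict_raw(df_alt),
                                      alt_allele, artifact.beta)
    e_mr = p_alt_ctx[:, r] / (p_alt_ctx[:, r] + p_alt_ctx[:, m])
    return e_rm, e_mr


# ---------------------------------------------------------------------------
# feature importance and selection
# ---------------------------------------------------------------------------

def _fold_assignments(table: TrainingTable, n_folds: int, seed: int) -> np.ndarray:
    """Fold index per row; folds cut along sample identifiers when possible."""
    df = table.df
    rng = np.random.default_rng(seed)
    if "sample" in df.columns and df["sample"].nunique() >= n_folds:
        samples = np.sort(df["sample"].unique())
        perm = rng.permutation(len(samples))
        fold_of_sample = {s: perm[i] % n_folds for i, s in enumerate(samples)}
        return df["sample"].map(fold_of_sample).to_numpy()
    return rng.integers(0, n_folds, size=len(df))


def _fit_and_score(df: pd.DataFrame, y: np.ndarray, schema: FeatureSchema,
                   tr: np.ndarray, va: np.ndarray, cfg: TrainConfig,
                   seed: int) -> float:
    dense, tnc = prepare_design(df, schema)
    model = build_network(schema, cfg.hidden_layout, seed=seed)
    model.fit(dense[tr], None if tnc is None else tnc[tr], y[tr],
              X_val=dense[va], tnc_val=None if tnc is None else tnc[va],
              y_val=y[va], config=cfg, seed=seed + 1)
    return model.nll(dense[va], None if tnc is None else tnc[va], y[va])


def loco_importance(table: TrainingTable, schema: FeatureSchema | None = None,
                    n_folds: int = 5, config: TrainConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Leave-one-covariate-out importance with k-fold cross-validation.

    For each fold a full model and one model per left-out feature are
    trained; the importance of a feature is the mean increase in validation
    NLL when it is removed.  Leaving out the trinucleotide context supplies
    the central reference base as a plain categorical feature instead, so
    only the neighbouring-base information is withheld.  Returns a frame
    with one row per feature, per-fold loss deltas, the mean delta and the
    rank (1 = most important), sorted most-important first.
    """
    cfg = config or TrainConfig()
    if schema is None:
        schema = FeatureSchema.from_table(table.df)
    feats = schema.feature_names
    if len(feats) < 2:
        raise ValueError("LOCO needs at least two features")
    df, y = table.df, table.df["obs_allele"].map(ALLELE_INDEX).to_numpy(np.int64)
    folds = _fold_assignments(table, n_folds, seed)
    deltas = {f: [] for f in feats}
    for k in range(n_folds):
        va = np.flatnonzero(folds == k)
        tr = np.flatnonzero(folds != k)
        if len(np.unique(y[tr])) < 2 or len(va) == 0:
            import warnings
            warnings.warn(f"fold {k} degenerate; skipped")
            continue
        base = _fit_and_score(df, y, schema, tr, va, cfg, seed + 100 * k)
        for f in feats:
            nll = _fit_and_score(df, y, schema.drop(f), tr, va, cfg,
                                 seed + 100 * k)
            deltas[f].append(nll - base)
    rows = [{"feature": f, "fold_deltas": deltas[f],
             "mean_delta": float(np.mean(deltas[f])) if deltas[f] else np.nan}
            for f in feats]
    out = pd.DataFrame(rows).sort_values("mean_delta", ascending=False,
                                         kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def stepwise_selection(table: TrainingTable, ranking: pd.DataFrame,
                       schema: FeatureSchema | None = None,
                       n_folds: int = 5, config: TrainConfig | None = None,
                       seed: int = 0) -> FeatureSchema:
    """Drop features cumulatively, least important first.

    A feature is kept only if removing it from the current model increases
    validation loss in *every* fold relative to the full-model baseline;
    otherwise it is removed permanently.  Returns the smallest surviving
    schema.
    """
    cfg = config or TrainConfig()
    if schema is None:
        schema = FeatureSchema.from_table(table.df)
    df, y = table.df, table.df["obs_allele"].map(ALLELE_INDEX).to_numpy(np.int64)
    folds = _fold_assignments(table, n_folds, seed)
    fold_sets = []
    for k in range(n_folds):
        va = np.flatnonzero(folds == k)
        tr = np.flatnonzero(folds != k)
        if len(np.unique(y[tr])) >= 2 and len(va) > 0:
            fold_sets.append((tr, va))
    baseline = [
        _fit_and_score(df, y, schema, tr, va, cfg, seed + 100 * k)
        for k, (tr, va) in enumerate(fold_sets)
    ]
    current = schema
    order = ranking.sort_values("rank", ascending=False)["feature"].tolist()
    for f in order:
        if len(current.feature_names) <= 1:
            break
        candidate = current.drop(f)
        losses = [
            _fit_and_score(df, y, candidate, tr, va, cfg, seed + 100 * k)
            for k, (tr, va) in enumerate(fold_sets)
        ]
        worse_in_all = all(l > b for l, b in zip(losses, baseline))
        if worse_in_all:
            break  # this and all more important features stay
        current = candidate
    return current
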