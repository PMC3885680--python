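"""Pairwise classification of finger movements from spectral PC weights.

Everything that is fitted — the ensemble normalizer, the per-channel spectral
basis, the r^2 channel selection, feature standardization and the classifier
hyperparameters — is fitted on training folds only and applied unchanged to
test folds.  The classifier is a max-margin binary classifier with a
radial-basis kernel; its penalty and kernel width are grid-searched on an
inner stratified split of the training data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import spectral, stats
from .types import NormalizedSpectrumSet, SpectrumSet

__all__ = ["DecodeConfig", "PairResult", "r2_map", "select_channels",
           "crossval_pairwise", "rest_control_decoding", "classify_cv",
           "make_procedure"]


@dataclass
class DecodeConfig:
    """Configuration of the pairwise decoding procedure."""

    pc_set: tuple[int, ...] = (0, 1, 2)
    n_feature_pcs: int = 5
    channel_strategy: str = "top_k"  # "fixed" | "top_k" | "threshold"
    fixed_channels: tuple[int, ...] = ()
    top_k: int = 10
    r2_threshold: float = 0.1
    folds: int = 5
    reps: int = 20
    inner_folds: int = 3
    c_exponents: tuple[int, ...] = tuple(range(-5, 16, 2))
    gamma_exponents: tuple[int, ...] = tuple(range(-15, 4, 2))
    exclude_line: bool = True
    line_freq: float = 60.0
    feature_mode: str = "pca"  # or "band"
    band: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.channel_strategy not in ("fixed", "top_k", "threshold"):
            raise ValueError(f"unknown strategy {self.channel_strategy!r}")
        if self.feature_mode not in ("pca", "band"):
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")
        if self.feature_mode == "band" and self.band is None:
            raise ValueError("band feature mode requires a band")
        if any(k < 0 or k >= self.n_feature_pcs for k in self.pc_set):
            raise ValueError("pc_set must index the first n_feature_pcs PCs")


@dataclass
class PairResult:
    """Decoding outcome for one finger pair."""

    pair: tuple[str, str]
    das: np.ndarray  # accuracy per repetition
    m: int  # total movements classified
    selected_channels: list = field(default_factory=list)  # per (rep, fold)
    guessing_ci: tuple[float, float] = (0.0, 1.0)

    @property
    def da_mean(self) -> float:
        return float(np.mean(self.das))

    @property
    def da_std(self) -> float:
        return float(np.std(self.das, ddof=1)) if len(self.das) > 1 else 0.0


def r2_map(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Proportion of variance explained by the group-mean difference.

    Equals the squared point-biserial correlation between the pooled feature
    values and a binary group indicator, computed independently along all
    trailing axes.  Zero total variance yields 0 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.shape[0], b.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    var = pooled.var(axis=0)
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    denom = (n1 + n2) ** 2 * var
    degenerate = denom <= 0
    if np.any(degenerate):
        warnings.warn("zero total variance: r^2 set to 0", RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(degenerate, 0.0,
                      n1 * n2 * mean_diff ** 2 / np.where(degenerate, 1.0,
                                                          denom))
    return np.clip(r2, 0.0, 1.0)


def select_channels(r2: np.ndarray, strategy: str = "top_k",
                    fixed: tuple[int, ...] = (), top_k: int = 10,
                    threshold: float = 0.1) -> np.ndarray:
    """Pick feature channels from a per-channel r^2 vector."""
    r2 = np.asarray(r2, dtype=float)
    if strategy == "fixed":
        if len(fixed) == 0:
            raise ValueError("fixed strategy requires a channel list")
        return np.asarray(sorted(fixed), dtype=int)
    if strategy == "top_k":
        k = min(top_k, r2.size)
        idx = np.argsort(r2, kind="stable")[::-1][:k]
        return np.sort(idx)
    if strategy == "threshold":
        idx = np.flatnonzero(r2 >= threshold)
        if idx.size == 0:
            warnings.warn("no channel above r^2 threshold; falling back to "
                          "the single best channel", RuntimeWarning)
            idx = np.array([int(np.argmax(r2))])
        return idx
    raise ValueError(f"unknown strategy {strategy!r}")


def _grid_search_svm(x: np.ndarray, y: np.ndarray, config: DecodeConfig,
                     rng: np.random.Generator) -> SVC:
    """Inner-CV grid search over (penalty, kernel width); refit the best."""
    best = (-np.inf, None)
    skf = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    splits = list(skf.split(x, y))
    for ce in config.c_exponents:
        for ge in config.gamma_exponents:
            c, g = 2.0 ** ce, 2.0 ** ge
            correct = 0
            for tr, te in splits:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(x[tr], y[tr])
                correct += int((clf.predict(x[te]) == y[te]).sum())
            if correct > best[0]:
                best = (correct, (c, g))
    c, g = best[1]
    clf = SVC(C=c, gamma=g, kernel="rbf")
    clf.fit(x, y)
    return clf


def _zscore_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def _fold_features_pca(psd: np.ndarray, train: np.ndarray, test: np.ndarray,
                       y: np.ndarray, context: np.ndarray | None,
                       freqs: np.ndarray, config: DecodeConfig):
    """Fit normalizer + basis + selection on train (+context); apply to test.

    Returns train features, test features and the selected channel indices.
    """
    fit_psd = psd[train]
    if context is not None and context.shape[0]:
        fit_psd = np.concatenate([fit_psd, context], axis=0)
    ens = fit_psd.mean(axis=0)

    def lognorm(p):
        dummy = np.full(p.shape[0], "", dtype=object)
        s = NormalizedSpectrumSet(np.log(p / ens), freqs, ens, dummy, dummy)
        return s

    basis = spectral.spectral_pca(lognorm(fit_psd),
                                  exclude_line=config.exclude_line,
                                  line_freq=config.line_freq,
                                  n_components=config.n_feature_pcs)
    w_tr = basis.weights[:train.size]  # grouped fit set starts with train
    w_te = spectral.project(basis, lognorm(psd[test]),
                            exclude_line=config.exclude_line,
                            line_freq=config.line_freq)
    k = config.n_feature_pcs
    y_tr = y[train]
    r2 = r2_map(w_tr[y_tr == 0][:, :, :k], w_tr[y_tr == 1][:, :, :k])
    r2_chan = r2.max(axis=-1)  # aggregate over PCs: keep the best PC
    chans = select_channels(r2_chan, config.channel_strategy,
                            config.fixed_channels, config.top_k,
                            config.r2_threshold)
    pcs = list(config.pc_set)
    f_tr = w_tr[:, chans][:, :, pcs].reshape(train.size, -1)
    f_te = w_te[:, chans][:, :, pcs].reshape(test.size, -1)
    return f_tr, f_te, chans


def _fold_features_band(feats: np.ndarray, train: np.ndarray,
                        test: np.ndarray, y: np.ndarray,
                        config: DecodeConfig):
    y_tr = y[train]
    r2 = r2_map(feats[train][y_tr == 0], feats[train][y_tr == 1])
    chans = select_channels(r2, config.channel_strategy,
                            config.fixed_channels, config.top_k,
                            config.r2_threshold)
    return feats[train][:, chans], feats[test][:, chans], chans


def _crossval(psd: np.ndarray, y: np.ndarray, context: np.ndarray | None,
              freqs: np.ndarray, config: DecodeConfig,
              rng: np.random.Generator,
              band_features: np.ndarray | None = None):
    """Repeated stratified k-fold; DA per repetition pooled over folds."""
    if len(np.unique(y)) != 2:
        raise ValueError("exactly two classes required")
    das = np.empty(config.reps)
    chosen: list[np.ndarray] = []
    for rep in range(config.reps):
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        correct = 0
        for train, test in skf.split(psd, y):
            if band_features is not None:
                f_tr, f_te, chans = _fold_features_band(
                    band_features, train, test, y, config)
            else:
                f_tr, f_te, chans = _fold_features_pca(
                    psd, train, test, y, context, freqs, config)
            chosen.append(chans)
            mu, sd = _zscore_fit(f_tr)
            clf = _grid_search_svm((f_tr - mu) / sd, y[train], config, rng)
            pred = clf.predict((f_te - mu) / sd)
            correct += int((pred == y[test]).sum())
        das[rep] = correct / y.size
    return das, chosen


def crossval_pairwise(spec_a: SpectrumSet, spec_b: SpectrumSet,
                      context: SpectrumSet | None,
                      config: DecodeConfig,
                      pair: tuple[str, str] = ("a", "b"),
                      alpha: float = 0.05) -> PairResult:
    """Decode finger A vs finger B movements with repeated cross-validation.

    ``context`` epochs (the pair's matched rest epochs) join the training
    data when fitting the normalizer and the spectral basis, but are never
    classified.  For band-power features the context is ignored.
    """
    if not np.array_equal(spec_a.freqs, spec_b.freqs):
        raise ValueError("frequency grids differ between groups")
    psd = np.concatenate([spec_a.psd, spec_b.psd], axis=0)
    y = np.concatenate([np.zeros(len(spec_a), dtype=int),
                        np.ones(len(spec_b), dtype=int)])
    rng = np.random.default_rng(config.seed)
    band_feats = None
    if config.feature_mode == "band":
        grouped = SpectrumSet(psd, spec_a.freqs,
                              np.concatenate([spec_a.condition,
                                              spec_b.condition]),
                              np.concatenate([spec_a.fingers,
                                              spec_b.fingers]))
        band_feats = spectral.band_power_features(grouped, config.band)
    ctx = context.psd if context is not None else None
    das, chosen = _crossval(psd, y, ctx, spec_a.freqs, config, rng,
                            band_features=band_feats)
    ci = stats.guessing_ci(y.size, alpha)
    return PairResult(pair=pair, das=das, m=int(y.size),
                      selected_channels=chosen, guessing_ci=ci)


def rest_control_decoding(rest_a: SpectrumSet, rest_b: SpectrumSet,
                          config: DecodeConfig,
                          pair: tuple[str, str] = ("a", "b"),
                          alpha: float = 0.05) -> PairResult:
    """Apply the identical pipeline to rest epochs labeled by the upcoming
    finger (control analysis: should sit at chance)."""
    if len(rest_a) == 0 or len(rest_b) == 0:
        raise ValueError("empty rest epoch set")
    return crossval_pairwise(rest_a, rest_b, None, config, pair, alpha)


def classify_cv(features: np.ndarray, labels: np.ndarray,
                config: DecodeConfig, rng: np.random.Generator) -> float:
    """Bare classification procedure on a fixed feature matrix.

    Stratified k-fold, per-fold standardization and grid-searched RBF
    classifier; returns pooled accuracy.  Used by the permutation test so the
    chance level is estimated with the same procedure as the real run.
    """
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    correct = 0
    for train, test in skf.split(features, labels):
        mu, sd = _zscore_fit(features[train])
        clf = _grid_search_svm((features[train] - mu) / sd, labels[train],
                               config, rng)
        pred = clf.predict((features[test] - mu) / sd)
        correct += int((pred == labels[test]).sum())
    return correct / labels.size


def make_procedure(config: DecodeConfig):
    """Adapter giving :func:`fingerdecode.stats.empirical_guessing` the same
    classification procedure used for the real decoding run."""
    def procedure(features: np.ndarray, labels: np.ndarray,
                  rng: np.random.Generator) -> float:
        return classify_cv(features, labels, config, rng)
    return procedure
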