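"""Delta-learning of the energy-correction model.

The model is fitted to reproduce the difference between reference and
baseline total energies,

    L = sum_i ((E_ref_i - E_base_i) - E_ML[rho_i])^2,

by full-batch Adam over the atomic-network parameters.  Raw invariants pass
through a per-species preprocessing pipeline fitted on the training split
only: a variance filter, standardization, and a principal-component
truncation retaining a configured explained-variance fraction gamma.

``iterative_train`` implements freeze-and-grow training: the functional
alters the self-consistent density, so a model fitted on baseline densities
is less accurate when deployed self-consistently; retraining on densities
made self-consistent with the previous iteration (freezing existing hidden
layers, appending one new one) closes that gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold

from .density import DensityField
from .model import EnergyModel, Pipeline, descriptors_from_density
from .network import Adam, AtomicNetwork
from .symmetry import DescriptorSet
from .system import AtomicSystem

logger = logging.getLogger("deltaxc.training")


@dataclass
class TrainingSample:
    """One delta-learning datum: geometry, density, and the energy pair."""

    system: AtomicSystem
    density: DensityField
    e_base: float
    e_ref: float

    @property
    def target(self) -> float:
        return self.e_ref - self.e_base


@dataclass
class TrainingConfig:
    gamma: float = 1.0                  # explained-variance retention
    variance_threshold: float = 1e-10
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    l2: float = 0.0                     # weight penalty (weights only)
    hidden: tuple[int, ...] = (8,)
    k_folds: int | None = None          # None -> 5 below 100 samples, else 3
    max_epochs: int = 4000
    tol: float = 0.0                    # stop when loss improvement < tol
    validation_fraction: float = 0.1
    patience: int = 200
    iter_tol: float = 0.01              # iterative-training relative MAE change
    iter_tol_abs: float = 1e-6          # Hartree floor for the same test
    max_iterations: int = 5
    batch_size: int | None = None       # None -> full batch
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")

    def folds_for(self, n: int) -> int:
        if self.k_folds is not None:
            return self.k_folds
        return 5 if n < 100 else 3


def delta_loss(e_ref, e_base, e_ml) -> float:
    """Sum of squared delta-learning residuals."""
    e_ref = np.asarray(e_ref, dtype=float).ravel()
    e_base = np.asarray(e_base, dtype=float).ravel()
    e_ml = np.asarray(e_ml, dtype=float).ravel()
    if not (e_ref.shape == e_base.shape == e_ml.shape):
        raise ValueError("energy vectors must have equal length")
    return float(np.sum(((e_ref - e_base) - e_ml) ** 2))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def fit_preprocessing(feature_matrices: dict[str, np.ndarray],
                      config: TrainingConfig,
                      like: dict[str, Pipeline] | None = None
                      ) -> dict[str, Pipeline]:
    """Fit the per-species variance-mask / scale / PCA pipelines.

    ``feature_matrices[species]`` stacks every training-atom invariant row of
    that species.  The retained principal-axis count is the smallest whose
    cumulative explained-variance ratio reaches gamma.

    With ``like`` (pipelines of a previous model) the statistics are refit
    on the new features but the variance mask and the retained axis count
    are inherited, so networks whose layers were trained against the old
    pipeline keep a compatible input dimension.
    """
    pipelines: dict[str, Pipeline] = {}
    for sym, D in feature_matrices.items():
        D = np.atleast_2d(np.asarray(D, dtype=float))
        if D.shape[0] < 2:
            raise ValueError(
                f"species {sym!r} has {D.shape[0]} sample(s); at least 2 "
                f"are required to fit the preprocessing")
        template = like.get(sym) if like else None
        if template is not None:
            mask = template.mask.copy()
        else:
            var = D.var(axis=0)
            mask = var >= config.variance_threshold
        if not np.any(mask):
            raise ValueError(f"species {sym!r}: every feature is constant")
        Dm = D[:, mask]
        mean = Dm.mean(axis=0)
        scale = Dm.std(axis=0)
        scale[scale == 0] = 1.0
        Z = (Dm - mean) / scale
        pca = PCA(n_components=None, svd_solver="full")
        pca.fit(Z)
        if template is not None:
            k = template.n_out
        elif config.gamma >= 1.0:
            k = Z.shape[1]
        else:
            cum = np.cumsum(pca.explained_variance_ratio_)
            k = int(np.searchsorted(cum, config.gamma) + 1)
        components = pca.components_[:k].T      # (n_kept, k)
        pipelines[sym] = Pipeline(mask=mask, mean=mean, scale=scale,
                                  components=components)
    return pipelines


def stack_features(descriptor_sets: list[DescriptorSet]) -> dict[str, np.ndarray]:
    """Per-species matrices of raw invariants over a list of structures."""
    rows: dict[str, list[np.ndarray]] = {}
    for ds in descriptor_sets:
        for a in range(ds.natoms):
            rows.setdefault(ds.species[a], []).append(ds.invariants[a])
    return {s: np.stack(r) for s, r in rows.items()}


def featurize(samples: list[TrainingSample], projector_factory,
              use_delta: bool = True) -> list[DescriptorSet]:
    """Project every sample's density into invariants.

    ``projector_factory(system, grid)`` returns a projection operator; it is
    called once per sample (caller may cache by geometry).
    """
    out = []
    for s in samples:
        proj = projector_factory(s.system, s.density.grid)
        out.append(descriptors_from_density(proj, s.density, use_delta))
    return out


# ---------------------------------------------------------------------------
# single training run
# ---------------------------------------------------------------------------

class TrainingError(RuntimeError):
    def __init__(self, message: str, epoch: int):
        super().__init__(f"{message} (epoch {epoch})")
        self.epoch = epoch


def _batched_design(descriptor_sets, pipelines):
    """Stack preprocessed features per species with sample scatter indices."""
    design = {}
    for sym, pipe in pipelines.items():
        X, idx = [], []
        for i, ds in enumerate(descriptor_sets):
            for a in range(ds.natoms):
                if ds.species[a] == sym:
                    X.append(ds.invariants[a])
                    idx.append(i)
        if X:
            design[sym] = (pipe.transform(np.stack(X)), np.asarray(idx))
    return design


def _predict(design, networks, n_samples):
    pred = np.zeros(n_samples)
    for sym, (X, idx) in design.items():
        np.add.at(pred, idx, networks[sym].predict(X))
    return pred


def train_once(descriptor_sets: list[DescriptorSet], targets: np.ndarray,
               config: TrainingConfig,
               model: EnergyModel | None = None,
               pipelines: dict[str, Pipeline] | None = None,
               basis_hash: str = "", use_delta: bool = True):
    """Fit (or continue fitting) an energy model by full-batch Adam.

    When ``model`` is given its networks are reused (frozen layers
    respected); otherwise fresh networks with ``config.hidden`` layers are
    built.  Pipelines are fitted here on the given training descriptors
    unless supplied.  Returns ``(EnergyModel, history)`` where history holds
    per-epoch training loss and the validation MAE trace.
    """
    targets = np.asarray(targets, dtype=float).ravel()
    n = len(descriptor_sets)
    if n == 0:
        raise ValueError("empty training set")
    if targets.shape[0] != n:
        raise ValueError("targets do not match descriptor count")
    rng = np.random.default_rng(config.seed)

    if pipelines is None:
        pipelines = fit_preprocessing(stack_features(descriptor_sets), config)
    if model is None:
        networks = {
            sym: AtomicNetwork(pipe.n_out, list(config.hidden), rng)
            for sym, pipe in pipelines.items()}
    else:
        networks = {sym: net.copy() for sym, net in model.networks.items()}

    # internal validation split for early stopping
    n_val = int(round(config.validation_fraction * n)) if n >= 10 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    ds_train = [descriptor_sets[i] for i in train_idx]
    y_train = targets[train_idx]
    design = _batched_design(ds_train, pipelines)
    if n_val:
        design_val = _batched_design([descriptor_sets[i] for i in val_idx],
                                     pipelines)
        y_val = targets[val_idx]

    params, masks, nets_order = [], [], sorted(design)
    for sym in nets_order:
        params.extend(networks[sym].parameters())
        masks.extend(networks[sym].trainable_mask())
    opt = Adam(params, lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2, mask=masks)

    history = {"loss": [], "val_mae": [], "best_epoch": 0}
    best_val, best_state, stall = np.inf, None, 0
    m = len(ds_train)
    for epoch in range(config.max_epochs):
        pred = _predict(design, networks, m)
        resid = pred - y_train
        loss = float(np.sum(resid ** 2))
        if not np.isfinite(loss):
            raise TrainingError("training diverged (non-finite loss)", epoch)
        grads = []
        for sym in nets_order:
            X, idx = design[sym]
            g = networks[sym].backprop(X, 2.0 * resid[idx])
            if config.l2:
                net = networks[sym]
                for i in range(len(net.weights)):
                    g[2 * i] = g[2 * i] + 2.0 * config.l2 * net.weights[i]
                    loss += config.l2 * float(np.sum(net.weights[i] ** 2))
            grads.extend(g)
        opt.step(grads)
        history["loss"].append(loss)
        if n_val:
            val_mae = float(np.mean(np.abs(
                _predict(design_val, networks, n_val) - y_val)))
            history["val_mae"].append(val_mae)
            if val_mae < best_val - 1e-15:
                best_val, stall = val_mae, 0
                best_state = {s: networks[s].copy() for s in networks}
                history["best_epoch"] = epoch
            else:
                stall += 1
                if stall > config.patience:
                    break
        if config.tol and epoch > 0 and \
                abs(history["loss"][-2] - loss) < config.tol:
            break
    if n_val and best_state is not None:
        networks = best_state
    logger.info("train_once: %d epochs, final loss %.3e, seed %d",
                len(history["loss"]), history["loss"][-1], config.seed)
    fitted = EnergyModel(pipelines=pipelines, networks=networks,
                         basis_hash=basis_hash, use_delta=use_delta)
    return fitted, history


def evaluate_mae(model: EnergyModel, descriptor_sets, targets) -> float:
    targets = np.asarray(targets, dtype=float).ravel()
    pred = np.array([model.energy(ds) for ds in descriptor_sets])
    return float(np.mean(np.abs(pred - targets)))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(descriptor_sets: list[DescriptorSet], targets: np.ndarray,
                   hyper_grid: list[dict], config: TrainingConfig,
                   basis_hash: str = "", use_delta: bool = True):
    """k-fold hyperparameter selection, then a final fit on all data.

    Fold assignment is deterministic from the seed.  The selected entry
    minimizes the mean validation MAE; exact ties go to the earlier grid
    entry.  Returns (final_model, selected_hypers, cv_table).
    """
    if not hyper_grid:
        raise ValueError("empty hyperparameter grid")
    targets = np.asarray(targets, dtype=float).ravel()
    n = len(descriptor_sets)
    k = config.folds_for(n)
    if n < k:
        raise ValueError(f"dataset of size {n} cannot be split into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=config.seed)
    splits = list(kf.split(np.arange(n)))

    table = []
    for gi, hypers in enumerate(hyper_grid):
        cfg = replace(config, **hypers)
        fold_mae = []
        for fi, (tr, va) in enumerate(splits):
            model, _ = train_once([descriptor_sets[i] for i in tr],
                                  targets[tr], cfg, basis_hash=basis_hash,
                                  use_delta=use_delta)
            mae = evaluate_mae(model, [descriptor_sets[i] for i in va],
                               targets[va])
            table.append({"grid_index": gi, "fold": fi, "val_mae": mae,
                          **hypers})
            fold_mae.append(mae)
        logger.info("cv: grid entry %d mean val MAE %.3e", gi,
                    float(np.mean(fold_mae)))
    means = [np.mean([row["val_mae"] for row in table
                      if row["grid_index"] == gi])
             for gi in range(len(hyper_grid))]
    best = int(np.argmin(means))       # argmin keeps the first on ties
    final_cfg = replace(config, **hyper_grid[best])
    final_model, _ = train_once(descriptor_sets, targets, final_cfg,
                                basis_hash=basis_hash, use_delta=use_delta)
    return final_model, hyper_grid[best], table


# ---------------------------------------------------------------------------
# iterative (freeze-and-grow) training
# ---------------------------------------------------------------------------

def iterative_train(scf_driver, samples: list[TrainingSample],
                    projector_factory, config: TrainingConfig,
                    basis_hash: str = "", use_delta: bool = True):
    """Freeze-and-grow training against a self-consistent driver.

    ``scf_driver(model, sample) -> (DensityField, float)`` returns the
    density and total energy obtained self-consistently with the current
    model for one training geometry (``model=None`` requests the baseline).

    Iteration 1 fits on the stored baseline densities.  Every further
    iteration re-projects densities made self-consistent with the previous
    model, freezes all existing hidden layers, appends one new hidden layer
    of the same width, and optimizes it (plus the head) on the updated
    descriptors.  Training stops when the self-consistent MAE changes by
    less than ``config.iter_tol`` (relative) between consecutive iterations.

    Returns (final_model, info) with per-iteration models and MAEs.
    """
    e_ref = np.array([s.e_ref for s in samples])
    targets0 = np.array([s.target for s in samples])

    desc = featurize(samples, projector_factory, use_delta)
    model, _ = train_once(desc, targets0, config, basis_hash=basis_hash,
                          use_delta=use_delta)
    models = [model]
    sc_mae: list[float] = []
    flagged: list[int] = []

    rng = np.random.default_rng(config.seed + 1)
    width = config.hidden[-1] if config.hidden else 8
    for iteration in range(1, config.max_iterations + 1):
        energies = np.empty(len(samples))
        densities: list[DensityField] = []
        ok = np.ones(len(samples), dtype=bool)
        for i, s in enumerate(samples):
            try:
                dens, e_tot = scf_driver(model, s)
            except RuntimeError:
                ok[i] = False
                flagged.append(i)
                dens, e_tot = s.density, s.e_base
            densities.append(dens)
            energies[i] = e_tot
        if not np.any(ok):
            raise TrainingError("self-consistency failed for every sample",
                                iteration)
        mae = float(np.mean(np.abs(energies[ok] - e_ref[ok])))
        sc_mae.append(mae)
        logger.info("iterative_train: iteration %d self-consistent MAE %.3e",
                    iteration, mae)
        if len(sc_mae) >= 2:
            prev = sc_mae[-2]
            if abs(mae - prev) <= max(config.iter_tol * prev,
                                      config.iter_tol_abs):
                break
        if iteration == config.max_iterations:
            break
        # re-project the self-consistent densities and grow the network
        new_samples = [replace(s, density=d)
                       for s, d in zip(samples, densities)]
        desc = featurize(new_samples, projector_factory, use_delta)
        pipelines = fit_preprocessing(stack_features(desc), config,
                                      like=model.pipelines)
        grown = {sym: net.grow(width, rng)
                 for sym, net in model.networks.items()}
        seed_model = EnergyModel(pipelines=pipelines, networks=grown,
                                 basis_hash=basis_hash, use_delta=use_delta)
        model, _ = train_once(desc, targets0, config, model=seed_model,
                              pipelines=pipelines, basis_hash=basis_hash,
                              use_delta=use_delta)
        models.append(model)
    best = int(np.argmin(sc_mae))      # never worse self-consistently than
    info = {"models": models, "sc_mae": sc_mae,   # the first iteration
            "flagged": sorted(set(flagged)), "iterations": len(sc_mae),
            "best_iteration": best + 1}
    return models[best], info
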