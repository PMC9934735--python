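"""The GCDM model object: training, sampling, likelihood, checkpoints.

``GCDM`` bundles the denoising network, the noise schedule, the fitted
molecule-size distribution and (for conditional models) the property
normalization statistics.  ``fit`` optimizes the ε-matching objective
½‖ε − ε̂‖² with uniformly sampled time steps and returns a ``FitResult``
carrying the loss history.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .autodiff import Tensor
from .denoiser import DenoiserConfig, DenoiserNetwork
from .diffusion import (NoiseSchedule, make_schedule, sample_molecules,
                        transition_coeffs, nll as _nll)
from .mol import (Molecule, SizeDistribution, fit_size_distribution,
                  remove_com, QM9_VOCAB)
from .nn import Adam

CHECKPOINT_VERSION = 1


@dataclass
class FitResult:
    """Outcome of ``GCDM.fit``: the trained model plus diagnostics."""

    model: "GCDM"
    loss_history: List[float] = field(default_factory=list)
    epochs: int = 0
    n_train: int = 0

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1] if self.loss_history else float("nan")

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "GCDM fit summary",
            "================",
            f"training molecules : {self.n_train}",
            f"epochs             : {self.epochs}",
            f"denoiser           : {cfg.n_layers} layers, "
            f"{cfg.node_scalar_dim}/{cfg.node_vector_channels} node dims",
            f"schedule           : {self.model.schedule.kind}, "
            f"T={self.model.schedule.T}",
            f"conditional        : {self.model.condition_name or 'no'}",
            f"first-epoch loss   : {self.loss_history[0]:.6f}"
            if self.loss_history else "first-epoch loss   : n/a",
            f"final loss         : {self.final_loss:.6f}",
        ]
        return "\n".join(lines)


class GCDM:
    """Joint coordinate/feature diffusion model over 3D molecules."""

    def __init__(self, config: Optional[DenoiserConfig] = None,
                 schedule: Optional[NoiseSchedule] = None,
                 vocab: Sequence[str] = QM9_VOCAB, seed: int = 0):
        self.config = config or DenoiserConfig()
        self.schedule = schedule or make_schedule("polynomial", 1000)
        self.vocab = tuple(vocab)
        self.seed = seed
        self.net = DenoiserNetwork(self.config, vocab=self.vocab, seed=seed)
        self.size_dist: Optional[SizeDistribution] = None
        self.condition_name: Optional[str] = None
        self.condition_stats = None          # (mean, std)
        self._opt: Optional[Adam] = None
        self._rng_state = None
        self._epochs_done = 0

    # -- conditioning ---------------------------------------------------------
    def standardize_condition(self, values) -> np.ndarray:
        if self.condition_stats is None:
            raise ValueError("model has no fitted condition statistics")
        mean, std = self.condition_stats
        return (np.asarray(values, dtype=np.float64) - mean) / std

    # -- training -------------------------------------------------------------
    def fit(self, mols: Sequence[Molecule], epochs: int = 50,
            batch_size: int = 64, lr: float = 1e-3,
            condition: Optional[str] = None, seed: int = 0,
            callback=None) -> FitResult:
        """Train the denoiser on a molecule list.

        ``condition`` names a key of ``property_labels``; when given, the
        property is standardized with training-set statistics and fed to
        every node of the graph (the network must have condition_dim=1).
        """
        if len(mols) == 0:
            raise ValueError("empty training set")
        self.size_dist = fit_size_distribution(mols)
        coords = [remove_com(m.coords) for m in mols]
        feats = [m.features() for m in mols]
        sizes = np.array([m.n_atoms for m in mols])

        cond_values = None
        if condition is not None:
            if self.config.condition_dim != 1:
                raise ValueError("conditional training needs condition_dim=1")
            vals = np.array([m.property_labels[condition] for m in mols])
            self.condition_name = condition
            self.condition_stats = (float(vals.mean()), float(vals.std()))
            cond_values = self.standardize_condition(vals)

        params = self.net.parameters()
        if self._opt is None:
            self._opt = Adam(params, lr=lr)
        else:
            self._opt.params = params
            self._opt.lr = lr
        opt = self._opt

        rng = np.random.default_rng(seed)
        if self._rng_state is not None:
            rng.bit_generator.state = self._rng_state

        T = self.schedule.T
        alphas = np.array([transition_coeffs(self.schedule, 0, t).alpha_ts
                           for t in range(1, T + 1)])
        sigmas = np.array([transition_coeffs(self.schedule, 0, t).sigma_ts
                           for t in range(1, T + 1)])

        history = []
        n = len(mols)
        for epoch in range(self._epochs_done, epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss = self._train_step(idx, coords, feats, sizes,
                                        cond_values, alphas, sigmas, rng, opt)
                losses.append(loss)
            history.append(float(np.mean(losses)))
            self._epochs_done = epoch + 1
            self._rng_state = rng.bit_generator.state
            if callback is not None:
                callback(epoch, history[-1])
        return FitResult(model=self, loss_history=history,
                         epochs=self._epochs_done, n_train=n)

    def _train_step(self, idx, coords, feats, sizes, cond_values,
                    alphas, sigmas, rng, opt) -> float:
        b = len(idx)
        seg = np.repeat(np.arange(b), sizes[idx])
        x0 = np.concatenate([coords[i] for i in idx], axis=0)
        h0 = np.concatenate([feats[i] for i in idx], axis=0)
        t_idx = rng.integers(0, self.schedule.T, size=b)   # t-1 per molecule
        a = alphas[t_idx][seg][:, None]
        s = sigmas[t_idx][seg][:, None]
        eps_x = rng.standard_normal(x0.shape)
        # project coordinate noise per molecule
        means = np.zeros((b, 3))
        np.add.at(means, seg, eps_x)
        eps_x = eps_x - (means / np.bincount(seg)[:, None])[seg]
        eps_h = rng.standard_normal(h0.shape)
        zx = a * x0 + s * eps_x
        zh = a * h0 + s * eps_h
        # re-center zx exactly (floating-point drift)
        mz = np.zeros((b, 3))
        np.add.at(mz, seg, zx)
        zx = zx - (mz / np.bincount(seg)[:, None])[seg]

        cond = cond_values[idx] if cond_values is not None else None
        t_frac = (t_idx + 1) / self.schedule.T
        ehat_x, ehat_h = self.net.forward(zx, zh, seg, t_frac, cond=cond)
        rx = ehat_x - Tensor(eps_x)
        rh = ehat_h - Tensor(eps_h)
        n_el = eps_x.size + eps_h.size
        loss = ((rx * rx).sum() + (rh * rh).sum()) * (0.5 / n_el)
        opt.zero_grad()
        loss.backward()
        opt.step()
        return float(loss.data)

    # -- generation -----------------------------------------------------------
    def sample(self, n_mols: int, rng: np.random.Generator,
               sizes: Optional[Sequence[int]] = None,
               condition_values=None, n_steps: Optional[int] = None,
               callback=None) -> List[Molecule]:
        """Generate molecules; sizes default to the fitted size distribution.

        ``condition_values`` are in native property units and are
        standardized with the stored training statistics.
        """
        cond = None
        if condition_values is not None:
            cv = np.asarray(condition_values, dtype=np.float64)
            if cv.ndim == 0:
                cv = np.full(n_mols, float(cv))
            cond = self.standardize_condition(cv)
        return sample_molecules(self.net, n_mols, self.schedule, rng,
                                sizes=sizes, size_dist=self.size_dist,
                                condition=cond, n_steps=n_steps,
                                callback=callback)

    def nll(self, mol: Molecule, n_mc: int = 1,
            rng: Optional[np.random.Generator] = None,
            full_sum: bool = False) -> float:
        """Variational bound on −log p(x, h, N) for one molecule."""
        if self.size_dist is None:
            raise ValueError("fit the model (or set size_dist) first")
        cond = None
        if self.condition_name is not None:
            val = mol.property_labels[self.condition_name]
            cond = self.standardize_condition([val])
        return _nll(self.net, mol, self.schedule, self.size_dist,
                    n_mc=n_mc, rng=rng, full_sum=full_sum, condition=cond)

    # -- checkpoints ----------------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file checkpoint: parameters, config, schedule, statistics."""
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "vocab": list(self.vocab),
            "schedule": {"kind": self.schedule.kind, "T": self.schedule.T,
                         "precision": self.schedule.precision},
            "condition_name": self.condition_name,
            "condition_stats": self.condition_stats,
            "seed": self.seed,
            "epochs_done": self._epochs_done,
            "rng_state": _jsonify(self._rng_state),
        }
        arrays = {f"param/{k}": v for k, v in self.net.state_dict().items()}
        if self.size_dist is not None:
            arrays["size/support"] = self.size_dist.support
            arrays["size/probs"] = self.size_dist.probs
        if self._opt is not None:
            arrays["opt/t"] = np.array(self._opt.t)
            for i, (m, v) in enumerate(zip(self._opt.m, self._opt.v)):
                arrays[f"opt/m{i}"] = m
                arrays[f"opt/v{i}"] = v
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str) -> "GCDM":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        model = cls(config=DenoiserConfig(**meta["config"]),
                    schedule=make_schedule(**meta["schedule"]),
                    vocab=meta["vocab"], seed=meta["seed"])
        model.net.load_state_dict(
            {k[len("param/"):]: data[k] for k in data.files
             if k.startswith("param/")})
        if "size/support" in data.files:
            model.size_dist = SizeDistribution(data["size/support"],
                                               data["size/probs"])
        model.condition_name = meta["condition_name"]
        if meta["condition_stats"] is not None:
            model.condition_stats = tuple(meta["condition_stats"])
        model._epochs_done = meta["epochs_done"]
        model._rng_state = _unjsonify(meta["rng_state"])
        if "opt/t" in data.files:
            opt = Adam(model.net.parameters())
            n_par = len(opt.params)
            opt.load_state_dict({
                "t": data["opt/t"],
                "m": [data[f"opt/m{i}"] for i in range(n_par)],
                "v": [data[f"opt/v{i}"] for i in range(n_par)],
            })
            model._opt = opt
        return model


def _jsonify(state):
    if state is None:
        return None
    return json.loads(json.dumps(state, default=int))


def _unjsonify(state):
    return state
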