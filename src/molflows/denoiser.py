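"""The denoiser contract and a small CPU-trainable implementation.

The denoiser maps the time-t state of a molecule (all modalities jointly) to
an estimate of the final molecule: position estimates plus per-modality class
probability distributions over *real* classes (the MASK class is never a
prediction target). The toy architecture is a feed-forward network over
per-atom features augmented with a mean-pooled molecule context, plus a
pairwise block for bond logits that sees the inter-atom distance; positions
are predicted as offsets from centered coordinates, which makes the model
translation-equivariant by construction. It is deliberately small — the
point is to exercise every flow variant end to end on a CPU, not to model
drug-like chemistry.

Gradients are written by hand (no autodiff dependency) and checked against
finite differences in the test suite; optimization uses Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .interpolants import (
    ModalityState,
    VariantId,
    onehot_rows,
    sample_conditional_path,
    sample_prior,
)
from .losses import (
    LossWeights,
    ce_loss,
    ce_loss_grad,
    regression_loss,
    regression_loss_grad,
    softmax,
    total_loss,
)
from .molgraph import MoleculeGraph, Vocabularies, pair_list

__all__ = [
    "GraphState",
    "DenoiserOutput",
    "ToyDenoiser",
    "MemorizationDenoiser",
    "TrainConfig",
    "train_toy_denoiser",
]


@dataclass
class GraphState:
    """Time-t state of one molecule across all modalities."""

    atoms: ModalityState
    charges: ModalityState
    bonds: ModalityState
    positions: np.ndarray  # (N, 3)

    @property
    def n_atoms(self) -> int:
        return self.atoms.n


@dataclass
class DenoiserOutput:
    """Predicted final molecule: positions plus logits over real classes."""

    positions_hat: np.ndarray  # (N, 3)
    atom_logits: np.ndarray  # (N, D_a)
    charge_logits: np.ndarray  # (N, D_c)
    bond_logits: np.ndarray  # (P, D_e)

    def check(self, n_atoms: int, n_pairs_: int) -> None:
        for name, arr, rows in (
            ("positions", self.positions_hat, n_atoms),
            ("atom_types", self.atom_logits, n_atoms),
            ("charges", self.charge_logits, n_atoms),
            ("bond_orders", self.bond_logits, n_pairs_),
        ):
            if arr.shape[0] != rows:
                raise ValueError(f"denoiser output for modality {name!r}: expected {rows} rows, got {arr.shape[0]}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"denoiser output for modality {name!r} contains non-finite values")


def _state_matrix(state: ModalityState, n_real: int, needs_mask: bool) -> np.ndarray:
    """Numeric matrix form of a modality state for the network input."""
    if state.indices is not None:
        return onehot_rows(state.indices, n_real + 1 if needs_mask else n_real)
    return state.vectors


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class ToyDenoiser:
    """Small feed-forward denoiser over fully connected molecular graphs."""

    def __init__(
        self,
        vocabs: Vocabularies,
        variant: VariantId,
        hidden: int = 64,
        hidden_pair: int = 64,
        hidden_pos: int = 32,
        rng: Union[int, np.random.Generator, None] = 0,
    ) -> None:
        self.vocabs = vocabs
        self.variant = VariantId(variant)
        self.hidden = hidden
        self.hidden_pair = hidden_pair
        self.hidden_pos = hidden_pos
        mask = self.variant is VariantId.CTMC
        self.da = vocabs.atoms.n_real
        self.dc = vocabs.charges.n_real
        self.de = vocabs.bonds.n_real
        self.da_in = self.da + (1 if mask else 0)
        self.dc_in = self.dc + (1 if mask else 0)
        self.de_in = self.de + (1 if mask else 0)
        self.n_geom = 5  # local distance summaries per atom
        # per-atom: categorical states + incident-bond sum + geometry + t
        f1 = self.da_in + self.dc_in + self.de_in + self.n_geom + 1
        ctx = self.da_in + self.dc_in + 1  # mean-pooled states + size
        self.f_node = f1 + ctx
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        h, hq, hp = hidden, hidden_pair, hidden_pos
        q_in = self.de_in + h + 2  # bond state + summed node embeddings + distance + t
        p_in = h + 3
        self.params: dict[str, np.ndarray] = {
            "W1": _glorot(rng, self.f_node, h),
            "b1": np.zeros(h),
            "Wa": _glorot(rng, h, self.da),
            "ba": np.zeros(self.da),
            "Wc": _glorot(rng, h, self.dc),
            "bc": np.zeros(self.dc),
            "W2": _glorot(rng, q_in, hq),
            "b2": np.zeros(hq),
            "We": _glorot(rng, hq, self.de),
            "be": np.zeros(self.de),
            "Wp": _glorot(rng, p_in, hp),
            "bp": np.zeros(hp),
            "Vp": _glorot(rng, hp, 3),
        }

    # -- introspection ---------------------------------------------------

    def describe(self) -> dict:
        counts = {k: int(v.size) for k, v in self.params.items()}
        return {
            "variant": self.variant.value,
            "n_parameters": int(sum(counts.values())),
            "per_tensor": counts,
            "hidden": self.hidden,
        }

    # -- forward / backward ---------------------------------------------

    def _forward(self, state: GraphState, t: float, want_cache: bool = False):
        n = state.n_atoms
        pairs = pair_list(n)
        mask = self.variant is VariantId.CTMC
        a_in = _state_matrix(state.atoms, self.da, mask)
        c_in = _state_matrix(state.charges, self.dc, mask)
        e_in = _state_matrix(state.bonds, self.de, mask)
        xt = np.asarray(state.positions, dtype=float)
        xbar = xt.mean(axis=0, keepdims=True)
        xc = xt - xbar

        # incident-bond context: per atom, sum of current bond states over its
        # pairs (scaled to valency range) -- a one-hop message pass
        bond_sum = np.zeros((n, e_in.shape[1]))
        np.add.at(bond_sum, pairs[:, 0], e_in)
        np.add.at(bond_sum, pairs[:, 1], e_in)
        bond_sum *= 0.25

        # local geometry summaries: three smallest neighbor distances (capped)
        # and neighbor counts at bonding radii
        if n > 1:
            dmat = np.linalg.norm(xc[:, None, :] - xc[None, :, :], axis=2)
            np.fill_diagonal(dmat, np.inf)
            dsort = np.sort(dmat, axis=1)
            k3 = np.minimum(dsort[:, : min(3, n - 1)], 5.0)
            if k3.shape[1] < 3:
                k3 = np.pad(k3, ((0, 0), (0, 3 - k3.shape[1])), constant_values=5.0)
            geom = np.concatenate(
                [k3, (dmat < 1.3).sum(axis=1, keepdims=True), (dmat < 1.8).sum(axis=1, keepdims=True)],
                axis=1,
            )
        else:
            geom = np.full((1, self.n_geom), 5.0)
            geom[:, 3:] = 0.0

        tcol = np.full((n, 1), float(t))
        f = np.concatenate([a_in, c_in, bond_sum, geom, tcol], axis=1)
        ctx = np.concatenate([a_in.mean(axis=0), c_in.mean(axis=0), [n / 20.0]])
        u_mat = np.concatenate([f, np.tile(ctx, (n, 1))], axis=1)
        z_pre = u_mat @ self.params["W1"] + self.params["b1"]
        z = np.tanh(z_pre)
        atom_logits = z @ self.params["Wa"] + self.params["ba"]
        charge_logits = z @ self.params["Wc"] + self.params["bc"]

        p_in = np.concatenate([z, xc], axis=1)
        hp = np.tanh(p_in @ self.params["Wp"] + self.params["bp"])
        dx = hp @ self.params["Vp"]
        positions_hat = xbar + xc + dx

        i_idx, j_idx = pairs[:, 0], pairs[:, 1]
        s = z[i_idx] + z[j_idx]
        dist = np.linalg.norm(xc[i_idx] - xc[j_idx], axis=1, keepdims=True)
        q = np.concatenate([e_in, s, dist, np.full((len(pairs), 1), float(t))], axis=1)
        y = np.tanh(q @ self.params["W2"] + self.params["b2"])
        bond_logits = y @ self.params["We"] + self.params["be"]

        out = DenoiserOutput(positions_hat, atom_logits, charge_logits, bond_logits)
        if not want_cache:
            return out, None
        cache = {"u_mat": u_mat, "z": z, "p_in": p_in, "hp": hp, "q": q, "y": y, "pairs": pairs}
        return out, cache

    def predict(self, state: GraphState, t: float) -> DenoiserOutput:
        """Denoiser contract: deterministic prediction of the final molecule."""
        if not 0.0 <= t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        out, _ = self._forward(state, t, want_cache=False)
        out.check(state.n_atoms, len(pair_list(state.n_atoms)))
        return out

    def backward(
        self,
        cache: dict,
        d_atom_logits: np.ndarray,
        d_charge_logits: np.ndarray,
        d_bond_logits: np.ndarray,
        d_positions: np.ndarray,
    ) -> dict[str, np.ndarray]:
        """Parameter gradients given output gradients (hand-written chain rule)."""
        p = self.params
        z, u_mat, p_in, hp, q, y, pairs = (
            cache["z"],
            cache["u_mat"],
            cache["p_in"],
            cache["hp"],
            cache["q"],
            cache["y"],
            cache["pairs"],
        )
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dz = np.zeros_like(z)

        # categorical heads
        grads["Wa"] = z.T @ d_atom_logits
        grads["ba"] = d_atom_logits.sum(axis=0)
        dz += d_atom_logits @ p["Wa"].T
        grads["Wc"] = z.T @ d_charge_logits
        grads["bc"] = d_charge_logits.sum(axis=0)
        dz += d_charge_logits @ p["Wc"].T

        # position head
        grads["Vp"] = hp.T @ d_positions
        dhp = d_positions @ p["Vp"].T
        dhp_pre = dhp * (1.0 - hp**2)
        grads["Wp"] = p_in.T @ dhp_pre
        grads["bp"] = dhp_pre.sum(axis=0)
        dz += (dhp_pre @ p["Wp"].T)[:, : z.shape[1]]

        # pair block
        grads["We"] = y.T @ d_bond_logits
        grads["be"] = d_bond_logits.sum(axis=0)
        dy = d_bond_logits @ p["We"].T
        dy_pre = dy * (1.0 - y**2)
        grads["W2"] = q.T @ dy_pre
        grads["b2"] = dy_pre.sum(axis=0)
        dq = dy_pre @ p["W2"].T
        ds = dq[:, self.de_in : self.de_in + z.shape[1]]
        np.add.at(dz, pairs[:, 0], ds)
        np.add.at(dz, pairs[:, 1], ds)

        # trunk
        dz_pre = dz * (1.0 - z**2)
        grads["W1"] = u_mat.T @ dz_pre
        grads["b1"] = dz_pre.sum(axis=0)
        return grads

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "variant": self.variant.value,
            "hidden": self.hidden,
            "hidden_pair": self.hidden_pair,
            "hidden_pos": self.hidden_pos,
            "atoms": list(self.vocabs.atoms.names),
            "atoms_mask": self.vocabs.atoms.mask_index,
            "charges": list(self.vocabs.charges.names),
            "charges_mask": self.vocabs.charges.mask_index,
            "bonds": list(self.vocabs.bonds.names),
            "bonds_mask": self.vocabs.bonds.mask_index,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "ToyDenoiser":
        from .molgraph import Vocabulary

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        vocabs = Vocabularies(
            atoms=Vocabulary(tuple(meta["atoms"]), meta["atoms_mask"]),
            charges=Vocabulary(tuple(meta["charges"]), meta["charges_mask"]),
            bonds=Vocabulary(tuple(meta["bonds"]), meta["bonds_mask"]),
        )
        model = cls(
            vocabs,
            VariantId(meta["variant"]),
            hidden=meta["hidden"],
            hidden_pair=meta["hidden_pair"],
            hidden_pos=meta["hidden_pos"],
        )
        model.params = params
        return model


class MemorizationDenoiser:
    """Stub denoiser that always predicts one target molecule.

    Useful as the "perfect denoiser" in sampler tests: with a size sampler
    pinned to the target's atom count, every generated molecule must decode
    to the target.
    """

    def __init__(self, target: MoleculeGraph, logit_scale: float = 1e3) -> None:
        self.target = target
        self.vocabs = target.vocabs
        self.logit_scale = logit_scale

    def predict(self, state: GraphState, t: float) -> DenoiserOutput:
        g = self.target
        if state.n_atoms != g.n_atoms:
            raise ValueError("memorization denoiser requires the target's atom count")
        sc = self.logit_scale
        return DenoiserOutput(
            positions_hat=g.positions.copy(),
            atom_logits=sc * onehot_rows(g.atom_types, g.vocabs.atoms.n_real),
            charge_logits=sc * onehot_rows(g.charges, g.vocabs.charges.n_real),
            bond_logits=sc * onehot_rows(g.bond_orders, g.vocabs.bonds.n_real),
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Optimization settings for the toy denoiser."""

    hidden: int = 64
    hidden_pair: int = 64
    hidden_pos: int = 32
    lr: float = 5e-3
    batch_size: int = 32
    weights: LossWeights = field(default_factory=LossWeights)
    beta_max: float = 100.0


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softmax_mse_grad(logits: np.ndarray, target_onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """MSE between softmax(logits) and a one-hot target, with d/d logits."""
    p = softmax(logits)
    loss = float(np.mean((p - target_onehot) ** 2))
    dp = 2.0 * (p - target_onehot) / p.size
    dlogits = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    return loss, dlogits


def molecule_losses_and_grads(
    model: ToyDenoiser,
    g1: MoleculeGraph,
    t: float,
    rng: np.random.Generator,
    beta_max: float = 100.0,
    weights: LossWeights = LossWeights(),
):
    """Sample x_t for one molecule, run the denoiser, return losses and grads.

    Returns (per_modality_losses, param_grads) where the parameter gradients
    are of the weighted total loss for this molecule.
    """
    variant = model.variant
    n = g1.n_atoms
    pairs_n = len(pair_list(n))
    x1_pos = g1.positions - g1.positions.mean(axis=0, keepdims=True)

    def make_state(idx: np.ndarray, count: int, n_real: int) -> ModalityState:
        if variant is VariantId.CTMC:
            x1 = ModalityState(indices=idx)
            return sample_conditional_path(variant, None, x1, t, rng, mask_index=n_real)
        x0 = sample_prior(variant, count, n_real, rng)
        x1 = ModalityState(vectors=onehot_rows(idx, n_real))
        return sample_conditional_path(variant, x0, x1, t, rng, beta_max=beta_max)

    atoms_t = make_state(g1.atom_types, n, model.da)
    charges_t = make_state(g1.charges, n, model.dc)
    bonds_t = make_state(g1.bond_orders, pairs_n, model.de)
    pos0 = sample_prior(VariantId.EUCLIDEAN, n, 3, rng)
    pos_t = (1.0 - t) * pos0.vectors + t * x1_pos
    state = GraphState(atoms_t, charges_t, bonds_t, pos_t)

    out, cache = model._forward(state, t, want_cache=True)

    losses: dict[str, float] = {}
    losses["X"] = regression_loss(out.positions_hat, x1_pos)
    d_pos = regression_loss_grad(out.positions_hat, x1_pos)
    if variant is VariantId.CTMC:
        losses["A"] = ce_loss(out.atom_logits, g1.atom_types)
        d_a = ce_loss_grad(out.atom_logits, g1.atom_types)
        losses["C"] = ce_loss(out.charge_logits, g1.charges)
        d_c = ce_loss_grad(out.charge_logits, g1.charges)
        losses["E"] = ce_loss(out.bond_logits, g1.bond_orders)
        d_e = ce_loss_grad(out.bond_logits, g1.bond_orders)
    elif variant is VariantId.CONTINUOUS:
        # unconstrained endpoint regression: the raw head IS the estimate
        ya = onehot_rows(g1.atom_types, model.da)
        yc = onehot_rows(g1.charges, model.dc)
        ye = onehot_rows(g1.bond_orders, model.de)
        losses["A"] = regression_loss(out.atom_logits, ya)
        d_a = regression_loss_grad(out.atom_logits, ya)
        losses["C"] = regression_loss(out.charge_logits, yc)
        d_c = regression_loss_grad(out.charge_logits, yc)
        losses["E"] = regression_loss(out.bond_logits, ye)
        d_e = regression_loss_grad(out.bond_logits, ye)
    else:
        # simplex-constrained variants: estimate lives on the simplex
        losses["A"], d_a = _softmax_mse_grad(out.atom_logits, onehot_rows(g1.atom_types, model.da))
        losses["C"], d_c = _softmax_mse_grad(out.charge_logits, onehot_rows(g1.charges, model.dc))
        losses["E"], d_e = _softmax_mse_grad(out.bond_logits, onehot_rows(g1.bond_orders, model.de))

    grads = model.backward(
        cache,
        weights.eta_a * d_a,
        weights.eta_c * d_c,
        weights.eta_e * d_e,
        weights.eta_x * d_pos,
    )
    return losses, grads


def train_toy_denoiser(
    dataset: list[MoleculeGraph],
    variant: VariantId,
    epochs: int,
    rng_seed: int = 0,
    config: Optional[TrainConfig] = None,
) -> tuple[ToyDenoiser, list[dict[str, float]]]:
    """Train the toy denoiser on a dataset; returns (model, loss history).

    The loss history holds, per epoch, the mean per-modality losses and the
    weighted total. Training is fully deterministic given ``rng_seed``.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if not dataset:
        raise ValueError("dataset must be non-empty")
    config = config or TrainConfig()
    variant = VariantId(variant)
    rng = np.random.default_rng(rng_seed)

    vocabs = dataset[0].vocabs
    if variant is VariantId.CTMC:
        vocabs_model = vocabs.with_mask()
    else:
        vocabs_model = vocabs
    model = ToyDenoiser(
        vocabs_model,
        variant,
        hidden=config.hidden,
        hidden_pair=config.hidden_pair,
        hidden_pos=config.hidden_pos,
        rng=rng,
    )
    opt = _Adam(model.params, config.lr)
    weights = config.weights
    history: list[dict[str, float]] = []
    n_data = len(dataset)

    for epoch in range(epochs):
        order = rng.permutation(n_data)
        epoch_losses = {"X": 0.0, "A": 0.0, "C": 0.0, "E": 0.0}
        n_seen = 0
        for start in range(0, n_data, config.batch_size):
            batch = order[start : start + config.batch_size]
            acc = {k: np.zeros_like(v) for k, v in model.params.items()}
            for mi in batch:
                t = float(rng.random())
                losses, grads = molecule_losses_and_grads(
                    model, dataset[mi], t, rng, beta_max=config.beta_max, weights=weights
                )
                for key, lv in losses.items():
                    if not np.isfinite(lv):
                        raise RuntimeError(
                            f"non-finite loss for modality {key!r} at epoch {epoch}, molecule {int(mi)}"
                        )
                    epoch_losses[key] += lv
                for k, gmat in grads.items():
                    acc[k] += gmat
                n_seen += 1
            for k in acc:
                acc[k] /= max(len(batch), 1)
            opt.step(model.params, acc)
        mean_losses = {k: v / max(n_seen, 1) for k, v in epoch_losses.items()}
        mean_losses["total"] = total_loss(mean_losses, weights)
        history.append(mean_losses)
    return model, history
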