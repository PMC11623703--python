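"""Generation-time integration: Euler steps, CTMC jumps, the full loop.

Sampling integrates the learned flow on an evenly spaced time grid
0 = t_0 < ... < t_K = 1 (Euler integration, 100 steps by default). The
continuous variants move vector states along the conditional vector field
built from the denoiser's endpoint estimate and discretize by argmax at
t = 1. The CTMC variant keeps purely discrete states: masked tokens unmask
with probability dt / (1 - t) per step (the rate implied by the linear
mixture path), drawing the revealed class from the denoiser distribution;
unmasked tokens are absorbing, and any mask surviving to the final step is
resolved by a forced draw so outputs are always mask-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Union

import numpy as np

from .denoiser import DenoiserOutput, GraphState
from .interpolants import (
    ModalityState,
    VariantId,
    conditional_vector_field,
    project_to_simplex,
    sample_prior,
)
from .losses import softmax
from .molgraph import MoleculeGraph, Vocabularies, n_pairs, validate_graph

__all__ = [
    "SamplerConfig",
    "GenerationTrajectory",
    "euler_step",
    "ctmc_step",
    "sample_sizes",
    "generate",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Integration protocol: variant for the categorical modalities, step count."""

    variant: VariantId = VariantId.CTMC
    n_steps: int = 100
    rng_seed: int = 0
    beta_max: float = 100.0
    record_trajectories: bool = False
    record_vectors: bool = False  # also keep raw vector states (continuous variants)

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_steps + 1)


@dataclass
class GenerationTrajectory:
    """Recorded per-token categorical trajectories of one generated molecule.

    For each categorical modality, ``states[m]`` and ``preds[m]`` are
    (n_tokens, K+1) integer arrays: the state of x_t (argmax for continuous
    variants, raw index for CTMC) and the argmax of the denoiser's predicted
    class distribution at every grid time. The final prediction column
    repeats the prediction that produced the final state.
    """

    grid: np.ndarray
    states: dict[str, np.ndarray]
    preds: dict[str, np.ndarray]
    vectors: Optional[dict[str, np.ndarray]] = None  # (n_tokens, K+1, D) raw states


def euler_step(x_t: np.ndarray, u: np.ndarray, dt: float) -> np.ndarray:
    """One explicit Euler step x_{t+dt} = x_t + dt * u."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return x_t + dt * np.asarray(u)


def ctmc_step(
    x_t: np.ndarray,
    p1_hat: np.ndarray,
    t: float,
    dt: float,
    rng: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """One CTMC transition for a vector of tokens.

    ``x_t`` holds class indices with the MASK class at index D (= number of
    columns of ``p1_hat``). Masked tokens unmask with probability
    dt / (1 - t); the revealed class is drawn from the denoiser distribution
    over real classes. Unmasked tokens are absorbing. When the step reaches
    t = 1, all remaining masks are resolved by a forced draw.
    """
    x_t = np.asarray(x_t, dtype=int)
    p1_hat = np.asarray(p1_hat, dtype=float)
    if t + dt > 1.0 + 1e-9:
        raise ValueError("t + dt must not exceed 1")
    row_sums = p1_hat.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("p1_hat rows must be normalized within 1e-6")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mask_index = p1_hat.shape[1]
    final = t + dt >= 1.0 - 1e-9
    p_unmask = 1.0 if final else min(dt / (1.0 - t), 1.0)

    out = x_t.copy()
    masked = x_t == mask_index
    if masked.any():
        unmask = rng.random(masked.sum()) < p_unmask
        rows = np.nonzero(masked)[0][unmask]
        if rows.size:
            cdf = np.cumsum(p1_hat[rows] / row_sums[rows, None], axis=1)
            r = rng.random(rows.size)
            out[rows] = (r[:, None] < cdf).argmax(axis=1)
    return out


def sample_sizes(
    size_histogram: Mapping[int, float],
    n: int,
    rng: Union[int, np.random.Generator, None] = None,
) -> list[int]:
    """i.i.d. molecule sizes from a (possibly unnormalized) histogram."""
    sizes = np.array(sorted(size_histogram.keys()), dtype=int)
    weights = np.array([size_histogram[int(s)] for s in sizes], dtype=float)
    if np.any(weights < 0):
        raise ValueError("histogram weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("histogram must have positive total mass")
    if n == 0:
        return []
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return [int(s) for s in rng.choice(sizes, size=n, p=weights / total)]


def _state_indices(state: ModalityState) -> np.ndarray:
    """Discrete summary of a modality state: raw indices or argmax."""
    if state.indices is not None:
        return state.indices.copy()
    return state.vectors.argmax(axis=1)


def _generate_one(
    denoiser,
    n_atoms: int,
    config: SamplerConfig,
    rng: np.random.Generator,
    vocabs: Vocabularies,
) -> tuple[MoleculeGraph, Optional[GenerationTrajectory]]:
    variant = VariantId(config.variant)
    k_steps = config.n_steps
    grid = config.grid
    dt = 1.0 / k_steps
    da, dc, de = vocabs.atoms.n_real, vocabs.charges.n_real, vocabs.bonds.n_real
    p = n_pairs(n_atoms)

    atoms = sample_prior(variant, n_atoms, da, rng)
    charges = sample_prior(variant, n_atoms, dc, rng)
    bonds = sample_prior(variant, p, de, rng)
    positions = sample_prior(VariantId.EUCLIDEAN, n_atoms, 3, rng).vectors

    rec = config.record_trajectories
    rec_vec = rec and config.record_vectors and variant is not VariantId.CTMC
    if rec:
        states_rec = {"atoms": [], "charges": [], "bonds": []}
        preds_rec = {"atoms": [], "charges": [], "bonds": []}
        vec_rec = {"atoms": [], "charges": [], "bonds": []}
    last_out: Optional[DenoiserOutput] = None

    for k in range(k_steps):
        t = float(grid[k])
        state = GraphState(atoms, charges, bonds, positions)
        out = denoiser.predict(state, t)
        out.check(n_atoms, p)
        last_out = out
        if variant is VariantId.CONTINUOUS:
            # unconstrained regression estimate: use the raw heads as x1_hat
            x1hat = {
                "atoms": out.atom_logits,
                "charges": out.charge_logits,
                "bonds": out.bond_logits,
            }
        else:
            x1hat = {
                "atoms": softmax(out.atom_logits),
                "charges": softmax(out.charge_logits),
                "bonds": softmax(out.bond_logits),
            }
        if rec:
            for name, st in (("atoms", atoms), ("charges", charges), ("bonds", bonds)):
                states_rec[name].append(_state_indices(st))
                preds_rec[name].append(x1hat[name].argmax(axis=1))
                if rec_vec:
                    vec_rec[name].append(st.vectors.copy())

        new = {}
        for name, st in (("atoms", atoms), ("charges", charges), ("bonds", bonds)):
            if variant is VariantId.CTMC:
                new[name] = ModalityState(indices=ctmc_step(st.indices, x1hat[name], t, dt, rng))
            else:
                u = conditional_vector_field(variant, st, x1hat[name], t, beta_max=config.beta_max)
                v = euler_step(st.vectors, u, dt)
                if variant in (VariantId.SIMPLEX, VariantId.DIRICHLET):
                    v = project_to_simplex(v)
                new[name] = ModalityState(vectors=v)
        atoms, charges, bonds = new["atoms"], new["charges"], new["bonds"]
        u_pos = (out.positions_hat - positions) / (1.0 - t)
        positions = euler_step(positions, u_pos, dt)

    atom_idx = _state_indices(atoms)
    charge_idx = _state_indices(charges)
    bond_idx = _state_indices(bonds)

    traj = None
    if rec:
        for name, idx, st in (
            ("atoms", atom_idx, atoms),
            ("charges", charge_idx, charges),
            ("bonds", bond_idx, bonds),
        ):
            states_rec[name].append(idx)
            preds_rec[name].append(preds_rec[name][-1])  # final prediction repeated at t=1
            if rec_vec:
                vec_rec[name].append(st.vectors.copy())
        traj = GenerationTrajectory(
            grid=grid.copy(),
            states={k: np.stack(v, axis=1) for k, v in states_rec.items()},
            preds={k: np.stack(v, axis=1) for k, v in preds_rec.items()},
            vectors={k: np.stack(v, axis=1) for k, v in vec_rec.items()} if rec_vec else None,
        )

    if vocabs.atoms.mask_index is not None:
        out_vocabs = Vocabularies(
            atoms=vocabs.atoms.without_mask(),
            charges=vocabs.charges.without_mask(),
            bonds=vocabs.bonds.without_mask(),
        )
    else:
        out_vocabs = vocabs
    g = MoleculeGraph(positions, atom_idx, charge_idx, bond_idx, out_vocabs)
    return g, traj


def generate(
    denoiser,
    n_mols: int,
    size_sampler: Union[Mapping[int, float], Callable[[np.random.Generator], int]],
    config: SamplerConfig = SamplerConfig(),
    rng: Union[int, np.random.Generator, None] = None,
) -> Union[list[MoleculeGraph], tuple[list[MoleculeGraph], list[GenerationTrajectory]]]:
    """Sample ``n_mols`` molecules by integrating the joint flow.

    ``size_sampler`` is a size histogram (atom-count -> weight) or a callable
    taking the generator and returning one size. Returns the molecules, or
    (molecules, trajectories) when ``config.record_trajectories`` is set.
    All outputs pass :func:`validate_graph`.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    vocabs = denoiser.vocabs
    if callable(size_sampler):
        sizes = [int(size_sampler(rng)) for _ in range(n_mols)]
    else:
        sizes = sample_sizes(size_sampler, n_mols, rng)
    mols: list[MoleculeGraph] = []
    trajs: list[GenerationTrajectory] = []
    for n_atoms in sizes:
        g, traj = _generate_one(denoiser, n_atoms, config, rng, vocabs)
        violations = validate_graph(g)
        if violations:
            raise RuntimeError(f"generated molecule violates graph invariants: {violations[0]}")
        mols.append(g)
        if traj is not None:
            trajs.append(traj)
    if config.record_trajectories:
        return mols, trajs
    return mols
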