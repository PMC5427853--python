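"""Helpers shared across test modules (importable, not fixtures)."""

from rlqspace.io import align_bundle, natural_log_transform
from rlqspace.ordination import gower_distance, patristic_distance
from rlqspace.spatial import aggregate_to_scale, mem_basis, partition


def bundle_at_scale(ds, scale: float):
    """Five-matrix bundle from a synthetic dataset at one quadrat scale,
    following the pipeline's preparation (log transform, MEM, Gower,
    patristic)."""
    grid, L = partition(ds.stem_map, scale)
    env = aggregate_to_scale(ds.env.values, ds.env.grid, grid)
    env_t, _ = natural_log_transform(env)
    traits_t, _ = natural_log_transform(ds.traits)
    mem = mem_basis(grid)
    T = gower_distance(traits_t)
    P = patristic_distance(ds.phylogeny)
    return align_bundle(L, env_t, mem.vectors, T, P)
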