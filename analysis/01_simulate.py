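#!/usr/bin/env python
"""Generate the synthetic datasets every later step consumes.

Emulated study conditions: partner counts for 20-38 hemibrains per
temperature at 12/18/25/31 °C (negative-binomial noise around the
exponential law with beta = 0.133), developmental times for 8-20 flies per
temperature (lognormal around alpha = 0.128), a three-glomerulus synapse
table with planted partner structure, and free-walking arena trajectories
with and without odor attraction.

Writes CSVs under results/data/.
"""

from pathlib import Path

from thermowire.synthetic import (
    GeneratorConfig,
    GlomerulusSpec,
    gen_devtimes,
    gen_partner_counts,
    gen_synapse_table,
    gen_trajectories,
)

OUT = Path("results/data")
SEED = 20250115

PARTNER_DESIGN = {12.0: 25, 18.0: 30, 25.0: 38, 31.0: 20}
DEVTIME_DESIGN = {12.0: 10, 18.0: 16, 25.0: 20, 31.0: 8}

GLOMERULI = [
    GlomerulusSpec(
        name="DM1", pre_type="Or42b",
        connections=[("orn1", "uPN_a", 60), ("orn2", "uPN_a", 55), ("orn1", "mPN_a", 18),
                     ("orn2", "LN_a", 12), ("orn1", "LN_b", 4), ("orn2", "weak", 2)],
        post_classes={"uPN_a": "uPN", "mPN_a": "mPN", "LN_a": "LN", "LN_b": "LN"},
    ),
    GlomerulusSpec(
        name="DL5", pre_type="Or7a",
        connections=[("orn3", "uPN_b", 48), ("orn4", "uPN_b", 40), ("orn3", "mPN_b", 14),
                     ("orn4", "LN_c", 11)],
        post_classes={"uPN_b": "uPN", "mPN_b": "mPN", "LN_c": "LN"},
    ),
    GlomerulusSpec(
        name="DM4", pre_type="Or59b",
        connections=[("orn5", "uPN_c", 52), ("orn5", "mPN_c", 16), ("orn5", "LN_d", 10)],
        post_classes={"uPN_c": "uPN", "mPN_c": "mPN", "LN_d": "LN"},
    ),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    partners = gen_partner_counts(GeneratorConfig(seed=SEED, design=PARTNER_DESIGN))
    partners.to_csv(OUT / "partner_counts.csv")
    print(f"partner counts: {len(partners.records)} hemibrains across "
          f"{partners.records.temperature_c.nunique()} temperatures")

    devtimes = gen_devtimes(GeneratorConfig(seed=SEED, design=DEVTIME_DESIGN))
    devtimes.to_csv(OUT / "devtimes.csv")
    print(f"developmental times: {len(devtimes.records)} flies")

    table = gen_synapse_table(GLOMERULI, coordinate_spread=1.0, separation=12.0, seed=SEED)
    table.to_csv(OUT / "synapse_table.csv", index=False)
    print(f"synapse table: {len(table)} synapses, {table.glomerulus_true.nunique()} glomeruli")

    for offset, (label, attraction) in enumerate([("odor", 0.6), ("control", 0.0)]):
        trajs = gen_trajectories(n_flies=15, frames=18000, attraction=attraction,
                                 seed=SEED + offset)
        trajs.positions.to_csv(OUT / f"trajectories_{label}.csv", index=False)
        print(f"trajectories ({label}): {trajs.n_flies} flies, "
              f"{trajs.duration_s / 60:.0f} min at {trajs.frame_rate:.0f} fps")


if __name__ == "__main__":
    main()
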