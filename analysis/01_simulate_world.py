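"""Generate the default synthetic world and summarise what it contains.

The world stands in for a results-tool extract: 10 locations x 2 years x
8 age bands x 2 sexes, three risk factors (BMI-like continuous harmful,
smoking-like categorical, fruit-intake-like protective) acting on three
cancer causes, with 1000 uncertainty draws and known ground-truth PAFs.
Writes the input tables under results/world/.
"""

from pathlib import Path

from craburden.synthetic import default_config, generate_world

OUT = Path(__file__).resolve().parents[1] / "results" / "world"


def main() -> None:
    cfg = default_config(seed=17, draws=1000)
    world = generate_world(cfg)
    OUT.mkdir(parents=True, exist_ok=True)

    keep = [c for c in world.exposures.columns if not c.startswith("draw_")]
    world.exposures[keep].to_csv(OUT / "exposure.csv", index=False)
    bkeep = [c for c in world.burden.columns if not c.startswith("draw_")]
    world.burden[bkeep].to_csv(OUT / "total_dalys.csv", index=False)
    world.sdi.to_csv(OUT / "sdi.csv", index=False)

    n_cells = len(world.truth.true_paf)
    print(f"world: {cfg.n_locations} locations x {len(cfg.years)} years x "
          f"{len(cfg.age_groups)} age bands x {len(cfg.sexes)} sexes, "
          f"{cfg.draws} draws (seed {cfg.seed})")
    print(f"risk-outcome cells with ground truth: {n_cells}")
    tp = list(world.truth.true_paf.values())
    print(f"true PAF range: {min(tp):.4f} .. {max(tp):.4f}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
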