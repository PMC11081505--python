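"""Train frequency groups of model neurons with ecological teacher ITDs.

Scaled-down version of the main developmental simulation: populations of
model neurons with best frequencies from 0.4 to 1.8 kHz are trained for
1,000 STDP updates with teacher ITDs drawn uniformly from 0 +- 0.13 ms (the
adult ecological range), and again with the unnatural range 0.6 +- 0.13 ms.
High-frequency neurons retune their best ITD into the teacher range within
the 1,000 updates; low-frequency neurons, whose dispersed input latencies
rarely push the summed potential past the plasticity threshold, barely move.

Writes results/population_teacher0.csv, results/population_teacher06.csv,
and a per-group summary results/population_summary.csv.
"""

from pathlib import Path

import pandas as pd

from msodev import pipeline

OUT = Path(__file__).resolve().parents[1] / "results"

N_PER_GROUP = 50  # scaled down from the 400-500 neurons per group figure runs
GROUPS = [{"best_freq": f, "n_neurons": N_PER_GROUP} for f in (0.4, 0.6, 1.0, 1.4, 1.8)]


def run(teacher, tag, seed):
    config = dict(
        command="simulate",
        groups=GROUPS,
        teacher_range=list(teacher),
        n_updates=1000,
        checkpoints=[1, 200, 400, 600, 800, 1000],
        seed=seed,
    )
    res = pipeline.run_simulate(config, OUT / f"population_{tag}")
    df = res["neurons"]
    df.to_csv(OUT / f"population_{tag}.csv", index=False)
    return df


def main() -> None:
    OUT.mkdir(exist_ok=True)
    summaries = []
    for teacher, tag, seed in [((-0.13, 0.13), "teacher0", 101),
                               ((0.47, 0.73), "teacher06", 102)]:
        df = run(teacher, tag, seed)
        centre = 0.5 * (teacher[0] + teacher[1])
        for bf, sub in df.groupby("group_khz"):
            init = sub[sub["update"] == 0]["bitd_ms"].mean()
            final = sub[sub["update"] == 1000]["bitd_ms"].mean()
            summaries.append(
                dict(teacher_ms=centre, group_khz=bf, init_mean_bitd_ms=init,
                     final_mean_bitd_ms=final,
                     distance_reduction=abs(init - centre) - abs(final - centre))
            )
        print(f"teacher {centre:+.2f} ms:")
        for s in summaries:
            if s["teacher_ms"] == centre:
                print(
                    f"  {s['group_khz']:.1f} kHz: bITD {s['init_mean_bitd_ms']:+.3f}"
                    f" -> {s['final_mean_bitd_ms']:+.3f} ms"
                )
    pd.DataFrame(summaries).to_csv(OUT / "population_summary.csv", index=False)


if __name__ == "__main__":
    main()
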