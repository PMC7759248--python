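"""Score the questionnaire responses into the per-scale variable catalogue.

Deduplicates repeated within-wave answers (keeping the latest), scores
each administration, and writes the long variable table to
results/scored_pro.csv.
"""

from pathlib import Path

from coqol.io import read_responses_csv
from coqol.pipeline import score_responses_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    responses = read_responses_csv(ROOT / "data" / "responses.csv")
    scored = score_responses_table(responses)
    scored.to_csv(ROOT / "scored_pro.csv", index=False)
    admins = scored[["participant_id", "scale_id", "wave"]].drop_duplicates()
    dropped = len({(r.participant_id, r.scale_id, r.wave, r.administration) for r in responses}) - len(admins)
    print(f"{len(admins)} administrations scored ({dropped} duplicate within-wave "
          f"answers discarded), {len(scored)} variable values -> {ROOT / 'scored_pro.csv'}")
    for scale, grp in scored.groupby("scale_id"):
        print(f"  {scale}: {grp['variable'].nunique()} distinct variables")


if __name__ == "__main__":
    main()
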