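"""Score a single name pair and unpack what the match value is made of.

Run:  python examples/score_pair.py
"""

from lasamatch import MatchParams, canonicalize, classify, match_value

local = canonicalize("TINYPHEN®")      # stored word: the local proprietary name
overseas = canonicalize("SINIPHEN")    # input: the overseas look-alike

score = match_value(local, overseas, MatchParams())

print(f"pair: {local.raw_label} vs {overseas.raw_label}")
print(f"bound letters (d = positional displacement):")
for p in score.binding.bound:
    print(f"  {p.letter}#{p.occurrence}: word pos {p.word_position}, "
          f"input pos {p.input_position}, d = {p.d:+.0f}")
print(f"unbound word letters: "
      f"{[f'{t.letter}#{t.occurrence}' for t in score.binding.unbound_word_tokens]}")
print(f"end-marker channels: {score.binding.marker_differences}")
print(f"superposition peak F* = {score.profile.f_star:.4f} at x = {score.profile.x_star:.4f}")
print(f"comparison letters l = {score.l_i:.0f}")
print(f"match value M = F*/l = {score.value:.4f}  ->  {score.percent:.0f}%  "
      f"({classify(score.percent)} confusion risk)")
# Six shared letters and the final-N marker all sit at displacement 0, so the
# peak counts 7 agreeing channels out of 10: M = 0.70, i.e. high-risk look-alikes.
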