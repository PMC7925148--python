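"""Train the naïve-Bayes sentiment dictionary and score new comments.

The dictionary tabulates P(word | category) with Laplace smoothing from a
hand-coded corpus; a new comment is scored by the geometric-mean likelihood
per category, normalized to q in [0, 1], and labelled where q >= 0.5.
"""

from sentits import build_dictionary, score_and_classify

coded_corpus = [
    ("brave doctor saved her", {"Support Doctor"}),
    ("kind doctor good care", {"Support Doctor"}),
    ("doctor careless rude", {"Blame Doctor"}),
    ("rude doctor ignored him", {"Blame Doctor"}),
    ("patient attacked staff shameful", {"Blame Patient"}),
    ("poor patient deserved better", {"Support Patient"}),
    ("society broken everywhere", {"Blame Big System"}),
    ("hospital fees absurd", {"Blame Medical System"}),
    ("media twisted the story", {"Blame Other"}),
    ("thanks to the nurses", {"Support Other"}),
    ("weather nice today", {"N/A"}),
]
# light smoothing: with a corpus this tiny, heavier smoothing would spread
# probability so evenly that no category could clear the 0.5 threshold
dictionary = build_dictionary(coded_corpus, alpha=0.05)
print(f"dictionary: {len(dictionary.vocabulary)} words x 9 categories")
print(f"P('rude' | Blame Doctor)    = {dictionary.prob('rude', 'Blame Doctor'):.3f}")
print(f"P('rude' | Support Doctor)  = {dictionary.prob('rude', 'Support Doctor'):.3f}")

for text in ("kind brave doctor", "rude careless doctor", "totally unrelated words"):
    score, labels = score_and_classify(dictionary, text, tau=0.5)
    top = max(score.as_dict().items(), key=lambda kv: kv[1])
    print(f"{text!r:32s} -> {sorted(labels)} (top q: {top[0]} {top[1]:.2f})")
print("q is the normalized per-category score; N/A means nothing passed 0.5")
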