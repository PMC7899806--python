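"""Independent hand-written oracle for the four outcome-normalization rules.

Deliberately implemented character-by-character with explicit loops and no
regular expressions, sharing no code with the package, so it can serve as an
independent cross-check of ctoutcomes.normalize.
"""

import string
import unicodedata

ASCII_PUNCT = set(string.punctuation)


def is_punct(ch):
    return ch in ASCII_PUNCT or unicodedata.category(ch)[0] == "P"


def split_words(text):
    """Maximal runs of non-space, non-punctuation characters."""
    words, current = [], []
    for ch in text:
        if ch.isspace() or is_punct(ch):
            if current:
                words.append("".join(current))
                current = []
        else:
            current.append(ch)
    if current:
        words.append("".join(current))
    return words


def is_subsequence(needle, haystack):
    it = iter(haystack)
    return all(ch in it for ch in needle)


def oracle_strip_abbreviation(text):
    trimmed = text
    while trimmed and trimmed[-1].isspace():
        trimmed = trimmed[:-1]
    if not trimmed or trimmed[-1] not in ")]":
        return text
    close = trimmed[-1]
    opener = "(" if close == ")" else "["
    # find the matching opener for the final bracket pair; token may not
    # itself contain brackets
    depth_chars = "()[]"
    i = len(trimmed) - 2
    while i >= 0 and trimmed[i] not in depth_chars:
        i -= 1
    if i < 0 or trimmed[i] != opener:
        return text
    token = trimmed[i + 1:-1]
    if any(ch.isspace() for ch in token):
        return text
    token_alnum = [ch.lower() for ch in token if ch.isalnum()]
    if len(token_alnum) < 2:
        return text
    head = trimmed[:i]
    initials = [w[0].lower() for w in split_words(head)]
    if not is_subsequence(token_alnum, initials):
        return text
    while head and head[-1].isspace():
        head = head[:-1]
    return head


def oracle_normalize(text):
    out = oracle_strip_abbreviation(text)
    out = out.lower()
    chars = [" " if is_punct(ch) else ch for ch in out]
    # collapse whitespace runs and trim
    tokens, current = [], []
    for ch in chars:
        if ch.isspace():
            if current:
                tokens.append("".join(current))
                current = []
        else:
            current.append(ch)
    if current:
        tokens.append("".join(current))
    return " ".join(tokens)
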