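# Cage sign-pattern table, version 1.
# Each cage carries 12 points, one per edge midpoint of the rectangular cage,
# each valued +1 or -1, summing to zero (six of each sign).
# Point slots 1-12 map to box-edge midpoints as documented in
# spectrophores.cage_model (top-face edges 1-4, vertical edges 5-8,
# bottom-face edges 9-12).
# The 12 non-stereospecific cages are, modulo the 24 proper rotations of the
# cage, exactly the 12 sign patterns equivalent to their own inversion image;
# the 18 stereospecific cages cover each of the 18 chiral pattern pairs once.
# Provenance: the published table, with one correction: the published
# non-stereospecific rows 2 and 3 are typeset identically; row 3 here is the
# pattern used by the reference OBSpectrophore implementation
# ("+++------+++"), which restores the 12 distinct inversion-closed classes.
# columns: id, stereospecific (0/1), signs (12 chars, + or -)
1	0	++---++---++
2	0	++--+--+--++
3	0	+++------+++
4	0	+++-----++-+
5	0	+++--+-+--+-
6	0	+++-+-+---+-
7	0	+++-+-+-+---
8	0	++++----+-+-
9	0	++++----++--
10	0	+++++--+----
11	0	++++++------
12	0	+++--+---+-+
13	1	++--+-+-+--+
14	1	+++-----+++-
15	1	+++--+----++
16	1	+++-+----+-+
17	1	+++-+-----++
18	1	+++-+---+-+-
19	1	+++-+---+--+
20	1	+++-++-----+
21	1	+++-++--+---
22	1	+++-+--+-+--
23	1	+++-+--+--+-
24	1	+++-+--+---+
25	1	+++-++-+----
26	1	+++-++----+-
27	1	+++-+-+--+--
28	1	+++-+++-----
29	1	+++++---+---
30	1	+++++----+--
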