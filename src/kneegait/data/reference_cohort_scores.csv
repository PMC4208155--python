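subject_id,timepoint,kss,oks,ucla,satisfaction
1,pre,38,18,7,
1,post,37,22,7,
2,pre,23,29,7,
2,post,91,44,7,
3,pre,33,28,8,
3,post,88,43,8,
4,pre,34,22,6,
4,post,80,35,6,
5,pre,44,34,7,
5,post,79,38,7,
6,pre,49,30,7,
6,post,82,36,7,
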