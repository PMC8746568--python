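{
 "table1_features.tsv": "775519ac52bbcaf22aa55ddc46c5c4a66e938660b261f63b502817689f159e54",
 "table1_fragments.tsv": "ea6487ce3f01eb5aa4cc9de9825afdd096f5d672edd753929887afc8cd0bb26e"
}
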