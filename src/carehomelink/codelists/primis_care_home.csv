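code,term,incentivised
160734000,Lives in a nursing home,Y
160737007,Lives in an old peoples' home,N
224224003,Lives in staffed home,N
394923006,Lives in a residential home,Y
248171000000108,Lives in care home,N
1024771000000108,Lives in hospice,N
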