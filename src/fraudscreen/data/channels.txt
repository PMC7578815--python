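Facebook
Facebook advertisement
Facebook post
Twitter
Twitter advertisement
Tweet
Friend or family member
Clinician
Support group
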